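"""Pipeline configuration with parse-time range validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Every stage parameter of the detection cascade, with defaults.

    Enhancement: ``levels`` (gray levels L), ``sets`` (optional fuzzy-set
    knot overrides).  Clustering: ``clusters`` c, ``fuzzifier`` w,
    ``rho`` convergence threshold (gray levels), ``theta_hard`` core
    membership threshold, ``gamma`` gravity dominance factor,
    ``cluster_max_iter``, ``roi_rule``, ``exclude_border``.  Refinement:
    ``beta``, ``lambda_``, ``nu``, ``sigma``, ``dt``, ``eps``, ``c0``,
    ``iters``, ``stop_tol``.  ``seed`` covers any stochastic toggles.
    """

    levels: int = 256
    sets: dict | None = None
    clusters: int = 4
    fuzzifier: float = 1.7
    rho: float = 0.01
    theta_hard: float = 0.85
    gamma: float = 2.0
    cluster_max_iter: int = 100
    roi_rule: str = "brightest"
    exclude_border: bool = False
    beta: float = 0.04
    lambda_: float = 5.0
    nu: float = 1.0
    sigma: float = 1.5
    dt: float = 5.0
    eps: float = 1.5
    c0: float = 8.0
    iters: int = 400
    min_iter: int = 300
    stop_tol: float = 2.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        checks = [
            ("levels", self.levels >= 2, "must be >= 2"),
            ("clusters", self.clusters >= 2, "must be >= 2"),
            ("fuzzifier", 1.4 < self.fuzzifier < 2.6, "must lie in (1.4, 2.6)"),
            ("rho", self.rho > 0, "must be positive"),
            ("theta_hard", 0.5 < self.theta_hard <= 1.0, "must lie in (0.5, 1]"),
            ("gamma", self.gamma >= 1.0, "must be >= 1"),
            ("cluster_max_iter", self.cluster_max_iter >= 1, "must be >= 1"),
            ("beta", 0.04 <= self.beta <= 0.1, "must lie in [0.04, 0.1]"),
            ("lambda", 2.0 <= self.lambda_ <= 6.0, "must lie in [2, 6]"),
            ("nu", 1.0 <= abs(self.nu) <= 3.5, "magnitude must lie in [1, 3.5]"),
            ("sigma", self.sigma > 0, "must be positive"),
            ("dt", self.dt > 0, "must be positive"),
            ("dt", self.beta * self.dt < 0.25,
             "beta * dt must stay below 0.25 for stability"),
            ("eps", self.eps > 0, "must be positive"),
            ("c0", self.c0 > 0, "must be positive"),
            ("iters", self.iters >= 1, "must be >= 1"),
            ("min_iter", 0 <= self.min_iter <= self.iters, "must lie in [0, iters]"),
            ("stop_tol", self.stop_tol > 0, "must be positive"),
        ]
        rule = self.roi_rule
        checks.append(("roi_rule",
                       rule == "brightest" or rule.startswith("index:"),
                       "must be 'brightest' or 'index:K'"))
        for key, ok, msg in checks:
            if not ok:
                raise ConfigError(f"{key}: {msg}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda"] = d.pop("lambda_")
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "lambda" in data:
            data["lambda_"] = data.pop("lambda")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> PipelineConfig:
    """Read a flat YAML key-value file; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration file must be a flat mapping")
    return PipelineConfig.from_dict(data)
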