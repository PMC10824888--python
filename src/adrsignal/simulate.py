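"""Synthetic spontaneous-report counts and the screening experiment harness.

The generator emulates the standard evaluation design for disproportionality
methods: a database of n reports, of which ``n_exposed`` mention the target
drug, and J ADR types whose stratum counts are independent binomial draws

    n_1j ~ Bin(n_exposed, p_exposed),   n_j - n_1j ~ Bin(n - n_exposed, p_unexposed).

With ``p_exposed == p_unexposed`` every flag is a false positive; with
``p_exposed > p_unexposed`` the flag rate is the sensitivity.  The drug-pair
variant draws the four exposure strata (neither / only drug 1 / only drug 2 /
both) independently with per-stratum incidence probabilities; the
multiplicative interaction being screened for is p00*p11 / (p10*p01).

Default sizes are the reference evaluation conditions: n = 10,000,000 total
reports, n_exposed = 10,000 (or 50,000), J = 100 (or 500) ADR types,
incidence probabilities a fraction of a percent, 1,000 replications.
Probabilities are specified in percent throughout, as such tables print them.

Reproducibility: each replicate draws from an independent substream keyed by
(seed, rep_index), so experiments can be re-run or parallelised without
changing any replicate's data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import screen as screen_mod
from .glmm import ConvergenceError
from .screen import ScreenConfig

__all__ = ["ScenarioSpec", "SimResult", "generate_single", "generate_ddi",
           "run_experiment", "SINGLE_NULL_SETTINGS", "SINGLE_SENSITIVITY_SETTINGS",
           "DDI_SETTINGS", "METHODS"]

METHODS = ("mixed-PRR", "mixed-ROR", "classic-PRR", "classic-ROR")

# Reference single-drug settings: false-positive runs use equal incidence in
# both strata (percent); sensitivity runs elevate the exposed stratum.
SINGLE_NULL_SETTINGS = [
    {"p_unexposed_pct": p, "p_exposed_pct": p, "n_exposed": n}
    for n in (10_000, 50_000) for p in (0.05, 0.1, 0.2)
]
SINGLE_SENSITIVITY_SETTINGS = [
    {"p_unexposed_pct": p0, "p_exposed_pct": p1, "n_exposed": 10_000}
    for p0, p1 in [(0.05, 0.075), (0.05, 0.1), (0.05, 0.125),
                   (0.1, 0.15), (0.1, 0.2), (0.1, 0.25)]
]
# Drug-pair settings keyed by scenario id; probabilities in percent for the
# strata (neither, only drug 1, only drug 2, both).  The "1-x" rows have
# multiplicative interaction ratio 1 (false-positive runs), the "2-x" rows
# have ratio > 1 (sensitivity runs).
DDI_SETTINGS = {
    "1-1a": (0.05, 0.05, 0.05, 0.05),
    "1-1b": (0.1, 0.1, 0.1, 0.1),
    "1-1c": (0.25, 0.25, 0.25, 0.25),
    "1-2a": (0.025, 0.025, 0.05, 0.05),
    "1-2b": (0.05, 0.05, 0.1, 0.1),
    "1-2c": (0.1, 0.1, 0.25, 0.25),
    "1-3a": (0.01, 0.025, 0.025, 0.0625),
    "1-3b": (0.025, 0.05, 0.05, 0.1),
    "1-3c": (0.05, 0.1, 0.1, 0.2),
    "2-1a": (0.025, 0.025, 0.025, 0.05),
    "2-1b": (0.05, 0.05, 0.05, 0.1),
    "2-1c": (0.1, 0.1, 0.1, 0.2),
    "2-2a": (0.01, 0.01, 0.025, 0.05),
    "2-2b": (0.025, 0.025, 0.05, 0.1),
    "2-2c": (0.05, 0.05, 0.1, 0.2),
    "2-3a": (0.01, 0.015, 0.015, 0.045),
    "2-3b": (0.02, 0.03, 0.03, 0.09),
    "2-3c": (0.04, 0.06, 0.06, 0.18),
}

DDI_STRATUM_SIZES = (10_000_000, 100_000, 100_000, 10_000)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation configuration (probabilities in percent)."""

    mode: str = "single"                    # "single" | "ddi"
    J: int = 100
    reps: int = 1000
    seed: int = 20240116
    # single-drug mode
    n_total: int = 10_000_000
    n_exposed: int = 10_000
    p_unexposed_pct: float = 0.05
    p_exposed_pct: float = 0.05
    # drug-pair mode
    stratum_sizes: tuple = DDI_STRATUM_SIZES
    p_pct: tuple = (0.05, 0.05, 0.05, 0.05)  # order: 00, 10, 01, 11

    def __post_init__(self):
        if self.mode not in ("single", "ddi"):
            raise ValueError("mode must be 'single' or 'ddi'")
        if self.mode == "single":
            probs = (self.p_unexposed_pct, self.p_exposed_pct)
            if not 0 < self.n_exposed < self.n_total:
                raise ValueError("need 0 < n_exposed < n_total")
        else:
            probs = self.p_pct
            if len(self.p_pct) != 4 or len(self.stratum_sizes) != 4:
                raise ValueError("ddi mode needs 4 probabilities and 4 stratum sizes")
            if min(self.stratum_sizes) <= 0:
                raise ValueError("stratum sizes must be positive")
        if not all(0 <= p / 100.0 < 1 for p in probs):
            raise ValueError("probabilities (percent) must lie in [0, 100)")
        if self.J < 1 or self.reps < 1:
            raise ValueError("J and reps must be positive")

    @classmethod
    def ddi(cls, scenario: str, **kwargs) -> "ScenarioSpec":
        """Named drug-pair scenario, e.g. ``ScenarioSpec.ddi("2-1c")``."""
        return cls(mode="ddi", p_pct=DDI_SETTINGS[scenario], **kwargs)

    @property
    def truly_elevated(self) -> bool:
        """Whether flags count as sensitivity (True) or false positives."""
        if self.mode == "single":
            return self.p_exposed_pct > self.p_unexposed_pct
        p00, p10, p01, p11 = (p / 100 for p in self.p_pct)
        return p00 * p11 > p10 * p01 * (1 + 1e-12)


@dataclass
class SimResult:
    """Flag-rate summary of one experiment."""

    spec: ScenarioSpec
    flag_rate_pct: dict = field(default_factory=dict)      # method -> %
    mc_se_pct: dict = field(default_factory=dict)          # method -> %
    reps_completed: dict = field(default_factory=dict)
    convergence_failures: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        spec = self.spec.__dict__.copy()
        spec["stratum_sizes"] = list(self.spec.stratum_sizes)
        spec["p_pct"] = list(self.spec.p_pct)
        return {"spec": spec, "flag_rate_pct": self.flag_rate_pct,
                "mc_se_pct": self.mc_se_pct,
                "reps_completed": self.reps_completed,
                "convergence_failures": self.convergence_failures}


def _rng(spec: ScenarioSpec, rep_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, rep_index)))


def _adr_labels(J: int) -> np.ndarray:
    return np.array([f"adr_{j + 1:04d}" for j in range(J)])


def generate_single(spec: ScenarioSpec, rep_index: int) -> pd.DataFrame:
    """One replicate of single-drug counts as a model-ready frame."""
    if spec.mode != "single":
        raise ValueError("spec.mode must be 'single'")
    rng = _rng(spec, rep_index)
    p1 = spec.p_exposed_pct / 100.0
    p0 = spec.p_unexposed_pct / 100.0
    n1 = spec.n_exposed
    n0 = spec.n_total - spec.n_exposed
    y1 = rng.binomial(n1, p1, size=spec.J)
    y0 = rng.binomial(n0, p0, size=spec.J)
    adrs = _adr_labels(spec.J)
    return pd.DataFrame({
        "stratum": np.repeat(["exposed", "unexposed"], spec.J),
        "adr": np.concatenate([adrs, adrs]),
        "count": np.concatenate([y1, y0]),
        "denominator": np.repeat([n1, n0], spec.J),
        "drug1": np.repeat([1, 0], spec.J),
    })


def generate_ddi(spec: ScenarioSpec, rep_index: int) -> pd.DataFrame:
    """One replicate of drug-pair counts (4 exposure strata per ADR)."""
    if spec.mode != "ddi":
        raise ValueError("spec.mode must be 'ddi'")
    rng = _rng(spec, rep_index)
    probs = [p / 100.0 for p in spec.p_pct]
    sizes = spec.stratum_sizes
    adrs = _adr_labels(spec.J)
    counts = [rng.binomial(sizes[s], probs[s], size=spec.J) for s in range(4)]
    x1 = (0, 1, 0, 1)
    x2 = (0, 0, 1, 1)
    labels = ("neither", "only_drug1", "only_drug2", "both")
    return pd.DataFrame({
        "stratum": np.repeat(labels, spec.J),
        "adr": np.tile(adrs, 4),
        "count": np.concatenate(counts),
        "denominator": np.repeat(sizes, spec.J),
        "drug1": np.repeat(x1, spec.J),
        "drug2": np.repeat(x2, spec.J),
    })


def _flags(frame: pd.DataFrame, method: str, mode: str,
           var_structure: str, alpha: float) -> np.ndarray:
    kind, measure = method.split("-")
    drugs = ("drug1",) if mode == "single" else ("drug1", "drug2")
    cfg = ScreenConfig(measure=measure.upper(), drugs=drugs, alpha=alpha,
                       var_structure=var_structure)
    if kind == "classic":
        table = screen_mod.screen_classic(frame, cfg)
    elif mode == "single":
        table = screen_mod.screen_single(frame, cfg)
    else:
        table = screen_mod.screen_ddi(frame, cfg)
    if mode == "ddi":  # the interaction signal is the screening target
        table = table[table["drug"] == "drug1*drug2"]
    return table["signal"].to_numpy(bool)


def run_experiment(spec: ScenarioSpec, methods=("classic-PRR",),
                   var_structure: str = "shared", alpha: float = 0.05,
                   progress: bool = False) -> SimResult:
    """Replicate generate -> screen -> flag and summarise flag rates.

    Replicates where the mixed-model engine fails to converge are counted in
    ``convergence_failures`` and excluded from that method's average (never
    silently dropped); a warning is raised if more than 5% fail.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    gen = generate_single if spec.mode == "single" else generate_ddi
    rates = {m: [] for m in methods}
    failures = {m: 0 for m in methods}
    for rep in range(spec.reps):
        frame = gen(spec, rep)
        for m in methods:
            try:
                flags = _flags(frame, m, spec.mode, var_structure, alpha)
                rates[m].append(flags.mean())
            except ConvergenceError:
                failures[m] += 1
        if progress and (rep + 1) % 50 == 0:
            print(f"  replicate {rep + 1}/{spec.reps}", flush=True)
    result = SimResult(spec=spec)
    for m in methods:
        done = len(rates[m])
        result.reps_completed[m] = done
        result.convergence_failures[m] = failures[m]
        if failures[m] > 0.05 * spec.reps:
            warnings.warn(f"{m}: {failures[m]}/{spec.reps} replicates failed "
                          "to converge", RuntimeWarning)
        if done:
            arr = 100.0 * np.asarray(rates[m])
            result.flag_rate_pct[m] = float(arr.mean())
            result.mc_se_pct[m] = float(arr.std(ddof=1) / np.sqrt(done)) if done > 1 else float("nan")
    return result
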