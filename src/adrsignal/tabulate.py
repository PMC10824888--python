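"""Contingency structures for spontaneous-report data.

A spontaneous reporting system stores one row per report, each mentioning a
set of suspected drugs and a set of adverse-reaction (ADR) terms.  Signal
detection summarises a (drug, ADR) pair in a 2x2 contingency table

    ==============  ===========  ==========  =======
    reports         ADR j        all others  total
    ==============  ===========  ==========  =======
    drug i          n_ij         n_i. - n_ij  n_i.
    all others      n_.j - n_ij  ...          n - n_i.
    ==============  ===========  ==========  =======

and a drug pair in the analogous four-stratum layout (neither / only drug 1 /
only drug 2 / both).  This module builds those structures from report-level
data and materialises the long-format count table that the model fits
consume: one row per (exposure stratum, ADR) with an event count, the
stratum denominator, and 0/1 drug-indicator covariates.

Counting conventions: the unit is the report.  A report mentioning drug ``i``
and ADR ``j`` contributes once to ``n_ij`` no matter how many times the term
repeats; ``n_i.`` is the number of reports mentioning drug ``i`` and ``n`` the
total number of reports.  This keeps every count bounded by its denominator
so the binomial/Poisson models downstream are well defined.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DRUG_PREFIX = "drug:"
ADR_PREFIX = "adr:"

__all__ = [
    "ContingencyTable",
    "build_contingency",
    "to_counts_frame",
    "read_reports",
    "read_counts",
    "validate_counts",
    "counts_to_contingency",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts for one (drug, ADR) pair.

    Attributes
    ----------
    n_joint : int
        Reports mentioning both the target drug and the ADR (``n_ij``).
    n_drug : int
        Reports mentioning the target drug (``n_i.``).
    n_adr : int
        Reports mentioning the ADR (``n_.j``).
    n_total : int
        All reports (``n``).
    """

    n_joint: int
    n_drug: int
    n_adr: int
    n_total: int

    def __post_init__(self):
        a, b, c, d = self.cells
        if min(a, b, c, d) < 0:
            raise ValueError(
                f"inconsistent contingency counts: a={a}, b={b}, c={c}, d={d} "
                "(all four cells must be non-negative)"
            )

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """The four cells (a, b, c, d) = (n_ij, n_i.-n_ij, n_.j-n_ij, rest)."""
        a = self.n_joint
        b = self.n_drug - self.n_joint
        c = self.n_adr - self.n_joint
        d = self.n_total - self.n_drug - self.n_adr + self.n_joint
        return a, b, c, d


def _flag_columns(reports: pd.DataFrame, prefix: str) -> list[str]:
    return [c for c in reports.columns if c.startswith(prefix)]


def _validate_reports(reports: pd.DataFrame) -> tuple[list[str], list[str]]:
    drug_cols = _flag_columns(reports, DRUG_PREFIX)
    adr_cols = _flag_columns(reports, ADR_PREFIX)
    if not drug_cols or not adr_cols:
        raise ValueError(
            "report frame needs 'drug:<name>' and 'adr:<name>' flag columns"
        )
    flags = reports[drug_cols + adr_cols]
    if not flags.isin([0, 1]).all().all():
        raise ValueError("drug/ADR flags must be 0/1")
    if (reports[adr_cols].sum(axis=1) < 1).any():
        bad = reports.index[reports[adr_cols].sum(axis=1) < 1][0]
        raise ValueError(f"report at index {bad} has no ADR flag set")
    return drug_cols, adr_cols


def build_contingency(reports: pd.DataFrame, drug: str, adr: str) -> ContingencyTable:
    """Count the 2x2 table for one (drug, ADR) pair from report-level data.

    ``reports`` must carry binary columns ``drug:<name>`` and ``adr:<name>``.
    """
    drug_cols, adr_cols = _validate_reports(reports)
    dcol, acol = DRUG_PREFIX + drug, ADR_PREFIX + adr
    if dcol not in drug_cols:
        raise KeyError(f"unknown drug label: {drug!r}")
    if acol not in adr_cols:
        raise KeyError(f"unknown ADR label: {adr!r}")
    d = reports[dcol].to_numpy(dtype=bool)
    a = reports[acol].to_numpy(dtype=bool)
    return ContingencyTable(
        n_joint=int((d & a).sum()),
        n_drug=int(d.sum()),
        n_adr=int(a.sum()),
        n_total=int(len(reports)),
    )


def _strata_for(drugs: list[str], flags: np.ndarray) -> tuple[list[str], np.ndarray, list[dict]]:
    """Stratum label per report plus the covariate pattern of each stratum."""
    if len(drugs) == 1:
        labels = ["unexposed", "exposed"]
        assign = flags[:, 0].astype(int)
        covs = [{drugs[0]: 0}, {drugs[0]: 1}]
    else:
        labels = ["neither", f"only_{drugs[0]}", f"only_{drugs[1]}", "both"]
        assign = flags[:, 0].astype(int) + 2 * flags[:, 1].astype(int)
        # order: (0,0), (1,0), (0,1), (1,1)
        covs = [
            {drugs[0]: 0, drugs[1]: 0},
            {drugs[0]: 1, drugs[1]: 0},
            {drugs[0]: 0, drugs[1]: 1},
            {drugs[0]: 1, drugs[1]: 1},
        ]
    return labels, assign, covs


def to_counts_frame(reports: pd.DataFrame, drugs: list[str]) -> pd.DataFrame:
    """Aggregate report-level data into the long-format model input.

    One row per (exposure stratum, ADR): for a single drug the two strata are
    exposed/unexposed; for a drug pair the four strata follow the covariate
    patterns (0,0), (1,0), (0,1), (1,1).  ADRs never reported in a stratum
    get an explicit zero row (they remain estimable under the mixed model).
    """
    if not 1 <= len(drugs) <= 2:
        raise ValueError("screening models are shipped for 1 or 2 drugs")
    drug_cols, adr_cols = _validate_reports(reports)
    for d in drugs:
        if DRUG_PREFIX + d not in drug_cols:
            raise KeyError(f"unknown drug label: {d!r}")
    flags = reports[[DRUG_PREFIX + d for d in drugs]].to_numpy(dtype=bool)
    labels, assign, covs = _strata_for(drugs, flags)
    adr_names = [c[len(ADR_PREFIX):] for c in adr_cols]
    adr_mat = reports[adr_cols].to_numpy(dtype=bool)

    rows = []
    for s, label in enumerate(labels):
        in_s = assign == s
        denom = int(in_s.sum())
        if denom == 0:
            raise ValueError(
                f"stratum {label!r} is empty; drop this drug combination "
                "(no reports carry that exposure pattern)"
            )
        counts = adr_mat[in_s].sum(axis=0)
        for adr, cnt in zip(adr_names, counts):
            rows.append({"stratum": label, "adr": adr, "count": int(cnt),
                         "denominator": denom, **covs[s]})
    frame = pd.DataFrame(rows)
    return frame


def counts_to_contingency(frame: pd.DataFrame, drug: str, adr: str) -> ContingencyTable:
    """Collapse a single-drug counts frame back to the 2x2 table of one ADR."""
    validate_counts(frame, covariates=[drug])
    sub = frame[frame["adr"] == adr]
    if sub.empty:
        raise KeyError(f"unknown ADR label: {adr!r}")
    exposed = sub[sub[drug] == 1]
    unexposed = sub[sub[drug] == 0]
    n_joint = int(exposed["count"].sum())
    n_drug = int(exposed["denominator"].sum())
    other = int(unexposed["count"].sum())
    n_unexp = int(unexposed["denominator"].sum())
    return ContingencyTable(n_joint=n_joint, n_drug=n_drug,
                            n_adr=n_joint + other, n_total=n_drug + n_unexp)


def validate_counts(frame: pd.DataFrame, covariates: list[str] | None = None) -> None:
    """Check the long-format invariants, naming the offending row on failure."""
    required = {"stratum", "adr", "count", "denominator"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"counts frame missing columns: {sorted(missing)}")
    bad = frame.index[frame["count"] > frame["denominator"]]
    if len(bad):
        raise ValueError(f"count exceeds denominator at row {bad[0]}")
    bad = frame.index[(frame["count"] < 0) | (frame["denominator"] <= 0)]
    if len(bad):
        raise ValueError(f"negative count or non-positive denominator at row {bad[0]}")
    per_stratum = frame.groupby("stratum")["denominator"].nunique()
    if (per_stratum > 1).any():
        raise ValueError(
            f"denominator not constant within stratum {per_stratum.idxmax()!r}"
        )
    dup = frame.duplicated(subset=["stratum", "adr"])
    if dup.any():
        raise ValueError(f"duplicate (stratum, adr) row at index {frame.index[dup][0]}")
    for cov in covariates or []:
        if cov not in frame.columns:
            raise ValueError(f"missing covariate column {cov!r}")
        if not frame[cov].isin([0, 1]).all():
            raise ValueError(f"covariate column {cov!r} must be 0/1")


def read_reports(path, sep: str = ",") -> pd.DataFrame:
    """Read report-level CSV/TSV: report_id plus drug:<name>/adr:<name> flags."""
    frame = pd.read_csv(path, sep=sep)
    if "report_id" not in frame.columns:
        raise ValueError("report file needs a 'report_id' column")
    _validate_reports(frame)
    return frame


def read_counts(path, sep: str = ",") -> pd.DataFrame:
    """Read an aggregated counts CSV/TSV (stratum, adr, count, denominator, x...)."""
    frame = pd.read_csv(path, sep=sep)
    validate_counts(frame)
    return frame
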