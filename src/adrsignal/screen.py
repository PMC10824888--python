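"""Per-ADR PRR/ROR screening models.

One fitted model yields the disproportionality measure for *every* ADR of a
target drug (or drug pair) simultaneously.  For the PRR the model is a
Poisson mixed model on stratum counts with offset log(denominator),

    log lambda_j(x) = beta_0 + b_0j + (beta_1 + b_1j) x ,

so the ADR-specific PRR is exp(beta_1 + b_1j); for the ROR the same linear
predictor sits on the logit scale of a binomial model with the stratum
denominator as trials, giving exp(beta_1 + b_1j) as the ADR-specific ROR.
For a drug pair the predictor gains main effects and a product term

    ... + (beta_2 + b_2j) x' + (beta_12 + b_12j) x x' ,

and exp(beta_12 + b_12j) is the multiplicative drug-drug-interaction signal.
Intervals for beta + b use the prediction variance from the mixed-model
equations, so every ADR gets a finite 95% CI -- including ADRs with a zero
cell, where the traditional measures cannot produce one.

``method="traditional"`` fits the comparator instead: an independent
fixed-effect GLM per ADR (equivalently the closed-form PRR/ROR and, for drug
pairs, the saturated two-factor-plus-interaction GLM).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import classic, tabulate
from .glmm import GLMM

__all__ = ["ScreenConfig", "SignalScreen", "SignalScreenResults",
           "screen_single", "screen_ddi", "screen_classic"]

TABLE_COLUMNS = ["drug", "adr", "measure", "estimate",
                 "ci_lower", "ci_upper", "signal", "method"]


@dataclass
class ScreenConfig:
    """Configuration of one screening run."""

    measure: str = "PRR"                  # "PRR" (Poisson) or "ROR" (binomial)
    drugs: tuple = ()
    alpha: float = 0.05
    method: str = "mixed"                 # "mixed" | "traditional"
    var_structure: str = "shared"
    engine_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.measure not in ("PRR", "ROR"):
            raise ValueError("measure must be 'PRR' or 'ROR'")
        if self.method not in ("mixed", "traditional"):
            raise ValueError("method must be 'mixed' or 'traditional'")
        if not 1 <= len(self.drugs) <= 2:
            raise ValueError("screening needs 1 or 2 drugs")


class SignalScreen:
    """Screening model over a long-format counts frame.

    Parameters
    ----------
    frame : DataFrame
        One row per (stratum, ADR): columns ``stratum, adr, count,
        denominator`` plus one 0/1 indicator column per drug.
    drugs : sequence of str
        One drug for single-drug screening, two for interaction screening;
        each must name an indicator column of ``frame``.
    """

    def __init__(self, frame: pd.DataFrame, drugs, measure: str = "PRR",
                 alpha: float = 0.05, method: str = "mixed",
                 var_structure: str = "shared", **engine_options):
        self.config = ScreenConfig(measure=measure, drugs=tuple(drugs),
                                   alpha=alpha, method=method,
                                   var_structure=var_structure,
                                   engine_options=engine_options)
        tabulate.validate_counts(frame, covariates=list(drugs))
        self.frame = frame.reset_index(drop=True)
        self.adrs = np.unique(self.frame["adr"])
        n_strata = self.frame["stratum"].nunique()
        expect = 2 ** len(drugs)
        if n_strata != expect:
            raise ValueError(
                f"{len(drugs)}-drug screening needs {expect} exposure strata, "
                f"got {n_strata}")
        if len(drugs) == 2:
            both = self.frame[(self.frame[drugs[0]] == 1)
                              & (self.frame[drugs[1]] == 1)]
            if both.empty or (both["denominator"] <= 0).any():
                raise ValueError("empty 'both drugs' stratum; cannot screen "
                                 "this drug combination")
        if self.config.method == "mixed" and len(self.adrs) < 2:
            raise ValueError(
                "mixed screening needs at least 2 ADRs to identify the "
                "variance components; use the traditional measures "
                "(adrsignal.classic) for a single ADR")

    @classmethod
    def from_reports(cls, reports: pd.DataFrame, drugs, **kwargs) -> "SignalScreen":
        return cls(tabulate.to_counts_frame(reports, list(drugs)), drugs, **kwargs)

    # ------------------------------------------------------------------

    def fit(self) -> "SignalScreenResults":
        cfg = self.config
        if cfg.method == "traditional":
            table = (self._classic_single() if len(cfg.drugs) == 1
                     else self._classic_ddi())
            return SignalScreenResults(self, table, glmm_results=None)
        table, res = (self._mixed_single() if len(cfg.drugs) == 1
                      else self._mixed_ddi())
        return SignalScreenResults(self, table, glmm_results=res)

    # -- mixed fits -----------------------------------------------------

    def _family(self):
        return "poisson" if self.config.measure == "PRR" else "binomial"

    def _glmm(self, X, fixed_names, random_terms):
        model = GLMM(
            self.frame["count"].to_numpy(float),
            self.frame["denominator"].to_numpy(float),
            X, self.frame["adr"].to_numpy(),
            random_terms=random_terms, family=self._family(),
            var_structure=self.config.var_structure,
            fixed_names=fixed_names)
        return model.fit(**self.config.engine_options)

    def _rows_from_combos(self, res, lf, term, drug_label):
        z = float(norm.ppf(1 - self.config.alpha / 2))
        combos = res.group_combos(lf, term)
        est = np.exp(combos["estimate"].to_numpy())
        lo = np.exp(combos["estimate"].to_numpy() - z * combos["se"].to_numpy())
        hi = np.exp(combos["estimate"].to_numpy() + z * combos["se"].to_numpy())
        return pd.DataFrame({
            "drug": drug_label, "adr": combos["group"],
            "measure": self.config.measure, "estimate": est,
            "ci_lower": lo, "ci_upper": hi,
            "signal": lo > 1.0, "method": "mixed"})

    def _mixed_single(self):
        (drug,) = self.config.drugs
        x = self.frame[drug].to_numpy(float)
        X = np.column_stack([np.ones_like(x), x])
        res = self._glmm(X, ["intercept", drug],
                         {"intercept": np.ones_like(x), "slope": x})
        table = self._rows_from_combos(res, [0.0, 1.0], "slope", drug)
        return table.reset_index(drop=True), res

    def _mixed_ddi(self):
        d1, d2 = self.config.drugs
        x1 = self.frame[d1].to_numpy(float)
        x2 = self.frame[d2].to_numpy(float)
        X = np.column_stack([np.ones_like(x1), x1, x2, x1 * x2])
        res = self._glmm(
            X, ["intercept", d1, d2, f"{d1}*{d2}"],
            {"intercept": np.ones_like(x1), "slope1": x1,
             "slope2": x2, "interaction": x1 * x2})
        parts = [
            self._rows_from_combos(res, [0, 1, 0, 0], "slope1", d1),
            self._rows_from_combos(res, [0, 0, 1, 0], "slope2", d2),
            self._rows_from_combos(res, [0, 0, 0, 1], "interaction", f"{d1}*{d2}"),
        ]
        return pd.concat(parts, ignore_index=True), res

    # -- traditional comparators ----------------------------------------

    def _cells_single(self):
        (drug,) = self.config.drugs
        piv = self.frame.pivot_table(index="adr", columns=drug,
                                     values="count", aggfunc="sum")
        denom = self.frame.groupby(drug)["denominator"].first()
        a = piv[1].reindex(self.adrs).to_numpy(float)
        c = piv[0].reindex(self.adrs).to_numpy(float)
        return a, float(denom[1]), c, float(denom[0])

    def _classic_single(self):
        (drug,) = self.config.drugs
        a, n1, c, n0 = self._cells_single()
        if self.config.measure == "PRR":
            est, lo, hi = classic.prr_arrays(a, n1, c, n0, self.config.alpha)
        else:
            est, lo, hi = classic.ror_arrays(a, n1 - a, c, n0 - c,
                                             self.config.alpha)
        return pd.DataFrame({
            "drug": drug, "adr": self.adrs, "measure": self.config.measure,
            "estimate": est, "ci_lower": lo, "ci_upper": hi,
            "signal": np.isfinite(lo) & (lo > 1.0), "method": "traditional"})

    def _cells_ddi(self):
        """counts (J,4) and denominators (4,) in stratum order 00,10,01,11."""
        d1, d2 = self.config.drugs
        key = self.frame[d1].to_numpy(int) + 2 * self.frame[d2].to_numpy(int)
        counts = np.empty((len(self.adrs), 4))
        denoms = np.empty(4)
        for s in range(4):
            sub = self.frame[key == s]
            counts[:, s] = (sub.set_index("adr")["count"]
                            .reindex(self.adrs).to_numpy(float))
            denoms[s] = sub["denominator"].iloc[0]
        return counts, denoms

    def _classic_ddi(self):
        """Saturated per-ADR GLM with both factors and their interaction.

        With four cells and four parameters the GLM maximum-likelihood
        estimates are closed-form contrasts of cell rates (Poisson) or cell
        odds (binomial), with the usual Wald variances.
        """
        d1, d2 = self.config.drugs
        n, N = self._cells_ddi()
        z = float(norm.ppf(1 - self.config.alpha / 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.config.measure == "PRR":
                base = n / N
                var_term = 1.0 / n
            else:
                base = n / (N - n)
                var_term = 1.0 / n + 1.0 / (N - n)
            logr = np.log(base)
            specs = {  # label -> (log estimate, variance, cells involved)
                d1: (logr[:, 1] - logr[:, 0], var_term[:, 1] + var_term[:, 0],
                     [1, 0]),
                d2: (logr[:, 2] - logr[:, 0], var_term[:, 2] + var_term[:, 0],
                     [2, 0]),
                f"{d1}*{d2}": (logr[:, 3] - logr[:, 1] - logr[:, 2] + logr[:, 0],
                               var_term.sum(axis=1), [0, 1, 2, 3]),
            }
            parts = []
            for label, (lest, lvar, cells) in specs.items():
                ok = (n[:, cells] > 0).all(axis=1)
                if self.config.measure == "ROR":
                    ok &= ((N - n)[:, cells] > 0).all(axis=1)
                se = np.sqrt(lvar)
                est = np.exp(lest)
                lo = np.where(ok, np.exp(lest - z * se), np.nan)
                hi = np.where(ok, np.exp(lest + z * se), np.nan)
                parts.append(pd.DataFrame({
                    "drug": label, "adr": self.adrs,
                    "measure": self.config.measure,
                    "estimate": np.where(np.isfinite(est), est, np.where(np.isnan(est), 0.0, est)),
                    "ci_lower": lo, "ci_upper": hi,
                    "signal": np.isfinite(lo) & (lo > 1.0),
                    "method": "traditional"}))
        return pd.concat(parts, ignore_index=True)


class SignalScreenResults:
    """Signal table plus (for mixed fits) the underlying model results."""

    def __init__(self, model: SignalScreen, table: pd.DataFrame, glmm_results):
        self.model = model
        self.table = table[TABLE_COLUMNS]
        self.glmm_results = glmm_results

    @property
    def signals(self) -> pd.DataFrame:
        return self.table[self.table["signal"]]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            f"{cfg.measure} screen ({cfg.method}) for {', '.join(cfg.drugs)}: "
            f"{self.table['adr'].nunique()} ADRs, "
            f"{int(self.table['signal'].sum())} signals",
        ]
        if self.glmm_results is not None:
            lines.append(self.glmm_results.summary())
        return "\n".join(lines)

    def to_csv(self, path, sep: str = ",") -> None:
        self.table.to_csv(path, sep=sep, index=False,
                          float_format="%.6g", lineterminator="\n")


# ---------------------------------------------------------------------------
# functional surface


def screen_single(frame: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Mixed-model screen of one drug; returns the signal table."""
    return SignalScreen(frame, config.drugs, measure=config.measure,
                        alpha=config.alpha, method="mixed",
                        var_structure=config.var_structure,
                        **config.engine_options).fit().table


def screen_ddi(frame: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Mixed-model drug-pair screen (main effects + interaction signals)."""
    if len(config.drugs) != 2:
        raise ValueError("screen_ddi needs exactly two drugs")
    return SignalScreen(frame, config.drugs, measure=config.measure,
                        alpha=config.alpha, method="mixed",
                        var_structure=config.var_structure,
                        **config.engine_options).fit().table


def screen_classic(frame: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Traditional per-ADR comparator with the same output schema."""
    return SignalScreen(frame, config.drugs, measure=config.measure,
                        alpha=config.alpha, method="traditional").fit().table
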