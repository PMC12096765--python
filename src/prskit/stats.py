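"""Association and concordance statistics for comparing PRS vectors.

Implements the evaluation battery used to judge whether two scoring paths
agree and whether a score predicts a binary outcome:

* logistic association — intercept + slope maximum-likelihood logistic fit
  of outcome on (by default z-scored) PRS, reported as an odds ratio per
  standard deviation with a Wald 95% CI, plus the rank-based AUC;
* ``auc_rank`` — the Mann–Whitney probability that a random case outscores
  a random control, with midranks for ties (identical to the trapezoidal
  ROC AUC);
* Lin's concordance correlation coefficient,
  ccc = 2·rho·sigma_x·sigma_y / (sigma_x^2 + sigma_y^2 + (mu_x − mu_y)^2),
  which penalises location and scale shifts that Pearson's r forgives
  (moments use denominator n, Lin's original convention);
* ECDF utilities, including the supremum distance between two empirical
  CDFs over the pooled sample (the two-sample Kolmogorov–Smirnov statistic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, rankdata

from .errors import FormatError, SeparationError, StatisticsError

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeTable:
    """sample_id -> binary outcome (1 = case, 0 = control)."""

    entries: dict[str, int]

    def __post_init__(self) -> None:
        for sid, y in self.entries.items():
            if y not in (0, 1):
                raise StatisticsError(f"non-binary outcome {y!r} for sample {sid!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if not {"sample_id", "outcome"} <= set(df.columns):
            raise FormatError(
                f"{path}: phenotype table needs sample_id and outcome columns"
            )
        if df["sample_id"].duplicated().any():
            raise FormatError(f"{path}: duplicate sample IDs")
        return cls({row.sample_id: int(row.outcome) for row in df.itertuples(index=False)})

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {"sample_id": list(self.entries), "outcome": list(self.entries.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class AssociationReport:
    """Logistic-fit summary: OR (per SD when standardized) + Wald 95% CI + AUC."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    auc: float
    n_cases: int
    n_controls: int
    standardized: bool
    log_or: float = float("nan")
    log_or_se: float = float("nan")

    def summary(self) -> str:
        unit = "per SD" if self.standardized else "per score unit"
        return (
            f"OR {unit}: {self.odds_ratio:.4f} "
            f"[95% CI {self.ci_low:.4f}, {self.ci_high:.4f}]  "
            f"AUC: {self.auc:.4f}  "
            f"(cases {self.n_cases}, controls {self.n_controls})"
        )


@dataclass
class ConcordanceReport:
    """Agreement between two score vectors: Lin's CCC with its moments,
    Pearson r, and the ECDF supremum distance."""

    ccc: float
    pearson_r: float
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    ecdf_max_distance: float

    def summary(self) -> str:
        return (
            f"Lin's CCC: {self.ccc:.6f}  Pearson r: {self.pearson_r:.6f}\n"
            f"means: {self.mean_x:.6g} vs {self.mean_y:.6g}  "
            f"variances: {self.var_x:.6g} vs {self.var_y:.6g}\n"
            f"ECDF max distance: {self.ecdf_max_distance:.6f}"
        )


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise StatisticsError(f"{name} is empty")
    if not np.isfinite(arr).all():
        raise StatisticsError(f"{name} contains non-finite values")
    return arr


def lin_ccc(x, y) -> ConcordanceReport:
    """Lin's concordance correlation coefficient between paired vectors.

    Moments use denominator n.  Symmetric in (x, y); equals Pearson's r
    exactly when the two vectors share mean and variance, and is strictly
    smaller in magnitude otherwise.  If exactly one vector is constant the
    coefficient is 0 (no covariation is possible) and Pearson r is NaN;
    two constant vectors leave the statistic undefined and raise.
    """
    xa = _as_float_vector(x, "x")
    ya = _as_float_vector(y, "y")
    if xa.size != ya.size:
        raise StatisticsError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise StatisticsError("need at least 2 paired observations")
    mean_x, mean_y = float(xa.mean()), float(ya.mean())
    var_x = float(np.var(xa))  # denominator n
    var_y = float(np.var(ya))
    if var_x == 0.0 and var_y == 0.0:
        raise StatisticsError("both vectors are constant; CCC undefined")
    if var_x == 0.0 or var_y == 0.0:
        rho = float("nan")
        ccc = 0.0
    else:
        rho = float(pearsonr(xa, ya).statistic)
        ccc = 2.0 * rho * math.sqrt(var_x) * math.sqrt(var_y) / (
            var_x + var_y + (mean_x - mean_y) ** 2
        )
    return ConcordanceReport(
        ccc=ccc,
        pearson_r=rho,
        mean_x=mean_x,
        mean_y=mean_y,
        var_x=var_x,
        var_y=var_y,
        ecdf_max_distance=ecdf_max_distance(xa, ya),
    )


def auc_rank(scores, labels) -> float:
    """ROC AUC as the Mann–Whitney probability, midranks for ties.

    AUC = (R1 − n1(n1+1)/2) / (n1·n0) where R1 is the rank-sum of the
    cases in the pooled midranked scores.
    """
    s = _as_float_vector(scores, "scores")
    y = np.asarray(labels).ravel().astype(int)
    if s.size != y.size:
        raise StatisticsError("scores and labels length mismatch")
    if set(np.unique(y)) - {0, 1}:
        raise StatisticsError("labels must be binary 0/1")
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise StatisticsError("need at least one case and one control")
    ranks = rankdata(s)  # midranks
    r1 = float(ranks[y == 1].sum())
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def logistic_association(
    prs, outcome, standardize: bool = True
) -> AssociationReport:
    """Fit outcome ~ intercept + PRS by maximum-likelihood logistic regression.

    With ``standardize`` (default) the PRS is z-scored first, so
    exp(slope) is the odds ratio per standard deviation of PRS — the
    scale on which polygenic-score effect sizes are conventionally quoted.
    The 95% CI is Wald: exp(slope ± 1.96·SE).  Perfect separation or
    non-convergence raises :class:`SeparationError` rather than returning
    meaningless coefficients.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = _as_float_vector(prs, "prs")
    y = np.asarray(outcome).ravel().astype(int)
    if x.size != y.size:
        raise StatisticsError("prs and outcome length mismatch")
    if x.size < 10:
        raise StatisticsError(f"need n >= 10, got {x.size}")
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise StatisticsError("outcome must contain both classes")
    if standardize:
        sd = float(x.std())  # ddof=0, matching the CCC moment convention
        if sd == 0.0:
            raise StatisticsError("constant PRS cannot be standardized")
        x = (x - x.mean()) / sd
    design = sm.add_constant(x)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        raise SeparationError("perfect separation detected")
    if not res.mle_retvals.get("converged", False) or any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    ):
        raise SeparationError("logistic fit did not converge")
    slope = float(res.params[1])
    se = float(res.bse[1])
    if not (math.isfinite(slope) and math.isfinite(se)) or abs(slope) > 30:
        raise SeparationError(
            "degenerate logistic fit (separation suspected): "
            f"slope={slope!r}, SE={se!r}"
        )
    z = float(norm.ppf(0.975))
    return AssociationReport(
        odds_ratio=math.exp(slope),
        ci_low=math.exp(slope - z * se),
        ci_high=math.exp(slope + z * se),
        auc=auc_rank(prs, y),
        n_cases=n1,
        n_controls=n0,
        standardized=standardize,
        log_or=slope,
        log_or_se=se,
    )


def ecdf_points(x) -> list[tuple[float, float]]:
    """Right-continuous ECDF as (value, cumulative fraction) step points.

    One point per distinct value; fractions lie in (0, 1] and end at 1.
    """
    xa = np.sort(_as_float_vector(x, "x"))
    values, counts = np.unique(xa, return_counts=True)
    fracs = np.cumsum(counts) / xa.size
    return [(float(v), float(f)) for v, f in zip(values, fracs)]


def ecdf_max_distance(x, y) -> float:
    """Supremum of |ECDF_x − ECDF_y| over the pooled sample values
    (the two-sample Kolmogorov–Smirnov statistic)."""
    xa = np.sort(_as_float_vector(x, "x"))
    ya = np.sort(_as_float_vector(y, "y"))
    grid = np.concatenate([xa, ya])
    fx = np.searchsorted(xa, grid, side="right") / xa.size
    fy = np.searchsorted(ya, grid, side="right") / ya.size
    return float(np.max(np.abs(fx - fy)))


@dataclass
class ComparisonReport:
    """Full two-path comparison for one score: concordance between the two
    PRS vectors plus one association report per path."""

    concordance: ConcordanceReport
    association_a: AssociationReport
    association_b: AssociationReport
    n_samples: int

    def summary(self) -> str:
        return (
            f"Paired samples: {self.n_samples}\n"
            f"{self.concordance.summary()}\n"
            f"path A: {self.association_a.summary()}\n"
            f"path B: {self.association_b.summary()}"
        )

    def to_frame(self) -> pd.DataFrame:
        c = self.concordance
        rows = [
            ("n_samples", self.n_samples),
            ("ccc", c.ccc),
            ("pearson_r", c.pearson_r),
            ("mean_a", c.mean_x),
            ("mean_b", c.mean_y),
            ("var_a", c.var_x),
            ("var_b", c.var_y),
            ("ecdf_max_distance", c.ecdf_max_distance),
        ]
        for tag, rep in (("a", self.association_a), ("b", self.association_b)):
            rows += [
                (f"or_{tag}", rep.odds_ratio),
                (f"or_{tag}_ci_low", rep.ci_low),
                (f"or_{tag}_ci_high", rep.ci_high),
                (f"auc_{tag}", rep.auc),
            ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def compare_score_sets(a, b, phenotype: PhenotypeTable) -> ComparisonReport:
    """Compare two ScoreResult collections for the same score.

    Joins on sample_id (intersection of a, b, and the phenotype table,
    in sorted ID order), computes Lin's CCC and the ECDF distance between
    the two PRS vectors, and fits one logistic association per vector.
    """
    a_by_id = {r.sample_id: r.prs_sum for r in a}
    b_by_id = {r.sample_id: r.prs_sum for r in b}
    common = sorted(set(a_by_id) & set(b_by_id) & set(phenotype.entries))
    if not common:
        raise StatisticsError("no samples shared by both score sets and phenotype")
    xa = np.array([a_by_id[s] for s in common])
    xb = np.array([b_by_id[s] for s in common])
    y = np.array([phenotype.entries[s] for s in common])
    return ComparisonReport(
        concordance=lin_ccc(xa, xb),
        association_a=logistic_association(xa, y),
        association_b=logistic_association(xb, y),
        n_samples=len(common),
    )


def plot_ecdf_overlay(x, y, path: str, labels=("path A", "path B")) -> None:
    """Write an ECDF overlay plot of two score vectors to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for vec, label in ((x, labels[0]), (y, labels[1])):
        pts = ecdf_points(vec)
        vals = [p[0] for p in pts]
        fracs = [p[1] for p in pts]
        ax.step(vals, fracs, where="post", label=label)
    ax.set_xlabel("PRS")
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
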