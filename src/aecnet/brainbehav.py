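"""Brain–behaviour modelling and behavioural statistics utilities.

Node strength summarises a subject's connectivity within an observed
network: the sum of AEC values over the component edges incident to
each node, averaged over the component's node set to give the subject's
mean network strength. Mean strength is then modelled with a Gaussian
identity-link GLM on group, error count and their interaction,

    strength ~ group + errors + group:errors,

and interaction p-values are corrected across (network, band) models by
Benjamini–Hochberg FDR. Welch t-tests from summary statistics and 2×2
chi-square tests reproduce the demographic comparisons typically
reported alongside.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def node_strength(aec_matrix: np.ndarray, component_edges) -> tuple[dict, float]:
    """Per-node strength within a component, and the subject mean strength.

    strength(v) = sum of matrix entries over component edges incident to
    v; the mean is taken over the component's node set (every node with
    at least one component edge), not over all atlas nodes.
    """
    edges = [tuple(e) for e in component_edges]
    if not edges:
        raise ValueError("empty component: no edges to sum")
    m = np.asarray(aec_matrix, float)
    n = m.shape[0]
    strengths: dict[int, float] = {}
    for u, v in edges:
        if not (0 <= u < n and 0 <= v < n) or u == v:
            raise ValueError(f"edge ({u},{v}) invalid for a {n}-node matrix")
        strengths[u] = strengths.get(u, 0.0) + m[u, v]
        strengths[v] = strengths.get(v, 0.0) + m[u, v]
    mean = float(np.mean(list(strengths.values())))
    return strengths, mean


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Welch two-sample t statistic and Welch–Satterthwaite df from summaries.

    Returns the signed t for mean1 − mean2 and the (fractional) degrees
    of freedom. Reported integer df conventionally truncate the
    fractional value.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df)


def chi_square_2x2(table, continuity: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2×2 table, optional Yates correction.

    Returns (chi2, df=1, p). A zero row or column marginal is an error.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in the contingency table")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=continuity)
    return float(chi2), int(df), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def strength_glm(records: pd.DataFrame, error_type: str | None = None) -> pd.DataFrame:
    """Group × Error GLMs of mean network strength, FDR-corrected.

    Parameters
    ----------
    records : DataFrame
        One row per subject per (network, band) with columns
        ``group`` (two levels), ``strength`` (mean network strength),
        ``errors`` (error count), and ``network``/``band`` labels
        (constant columns may be omitted for a single model).
    error_type : str, optional
        Annotation copied to the output.

    Returns
    -------
    DataFrame with one row per (network, band): interaction
    coefficient, standard error, p-value and BH-FDR q across all
    models.
    """
    df = records.copy()
    for col, default in (("network", "net"), ("band", "band")):
        if col not in df.columns:
            df[col] = default
    required = {"group", "strength", "errors"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    rows = []
    for (network, band), sub in df.groupby(["network", "band"], sort=True):
        counts = sub.groupby("group")["errors"].count()
        if len(counts) != 2 or counts.min() < 3:
            raise ValueError(
                f"model ({network}, {band}) needs >= 3 subjects per group in 2 groups"
            )
        levels = sorted(sub["group"].unique())
        g = (sub["group"] == levels[1]).astype(float)
        e = sub["errors"].astype(float)
        x = pd.DataFrame(
            {
                "const": 1.0,
                "group": g.values,
                "errors": e.values,
                "group_x_errors": (g * e).values,
            }
        )
        if np.linalg.matrix_rank(x.values) < x.shape[1]:
            raise ValueError(
                f"perfect collinearity among group, errors, group:errors in "
                f"model ({network}, {band})"
            )
        model = sm.GLM(
            sub["strength"].astype(float).values,
            x.values,
            family=sm.families.Gaussian(),
        ).fit()
        rows.append(
            {
                "network": network,
                "band": band,
                "error_type": error_type,
                "beta": model.params[3],
                "se": model.bse[3],
                "p": model.pvalues[3],
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].values)
    return out
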