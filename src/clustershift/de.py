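"""Gene-wise linear models with empirical-Bayes moderated t-statistics.

Each tissue arm is fitted separately with cell-means (group indicator) coding
over the condition groups {0dpa, 3dpa_control, 8dpa_control, 3dpa_inhibitor,
8dpa_inhibitor}, so coefficients are group means.  Residual variances are
shrunk toward a common prior by moment matching on log s² — the scaled-F model
behind the moderated t — and pairwise contrasts are tested on the augmented
degrees of freedom d0 + d_g.

The "dynamic gene" filter keeps genes with unadjusted p < 0.05 in at least one
of the six pairwise stage comparisons (3v0, 8v0, 8v3 under each arm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .expression import ExpressionMatrix, SampleTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """Samples × coefficients indicator design with named coefficients."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        x = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValidationError("design matrix is rank deficient")

    @property
    def coef_names(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class ContrastSpec:
    name: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.any(self.vector):
            raise ValidationError(f"contrast {self.name!r} is all-zero")


@dataclass
class LinearFit:
    """Per-gene OLS fit under a shared design."""

    coefficients: pd.DataFrame   # genes × coefficients (group means)
    sigma2: pd.Series            # residual variance per gene
    df_residual: float
    design: DesignSpec
    xtx_inv: np.ndarray


@dataclass
class ModeratedVariances:
    d0: float                    # prior degrees of freedom (may be inf)
    s0_sq: float                 # prior variance
    posterior: pd.Series         # shrunken variances s~_g^2


def group_label(timepoint, treatment, baseline_timepoint) -> str:
    if timepoint == baseline_timepoint:
        return f"{timepoint}dpa"
    return f"{timepoint}dpa_{treatment}"


def build_design(samples: SampleTable) -> DesignSpec:
    """Cell-means indicator design over (timepoint, treatment) groups for one
    tissue arm; the baseline timepoint is a single shared group."""
    t = samples.table
    if t["tissue"].nunique() > 1:
        raise ValidationError("build_design expects a single-tissue sample table")
    t0 = min(t["timepoint_dpa"])
    groups = [group_label(r["timepoint_dpa"], r["treatment"], t0) for _, r in t.iterrows()]
    dummies = pd.get_dummies(pd.Series(groups, index=t.index), dtype=float)
    order = sorted(dummies.columns, key=lambda g: (g != f"{t0}dpa", g))
    dm = dummies[order]
    if (dm.sum(axis=0) == 0).any():
        raise ValidationError("a design group has zero samples")
    return DesignSpec(dm)


def fit_linear_models(expr: ExpressionMatrix, samples: SampleTable) -> LinearFit:
    """Ordinary least squares per gene; with indicator coding the coefficients
    are the group mean expressions."""
    design = build_design(samples)
    x = design.matrix.to_numpy(dtype=float)
    y = expr.values[design.matrix.index].to_numpy(dtype=float).T  # samples × genes
    n, p = x.shape
    df = n - p
    if df < 1:
        raise ValidationError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y                      # p × genes
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    return LinearFit(
        coefficients=pd.DataFrame(beta.T, index=expr.genes, columns=design.coef_names),
        sigma2=pd.Series(sigma2, index=expr.genes, name="sigma2"),
        df_residual=float(df),
        design=design,
        xtx_inv=xtx_inv,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def moderate_variances(sigma2: pd.Series, df: float,
                       d0_override: float | None = None) -> ModeratedVariances:
    """Moment-matching fit of the scaled-F prior on residual variances.

    Matches the mean and variance of log s² against the theoretical digamma /
    trigamma moments to estimate (d0, s0²); posterior variances are the
    df-weighted average  s̃² = (d0·s0² + d·s²)/(d0 + d).  ``d0_override=0``
    disables shrinkage (classical t); all-equal variances give d0 = ∞.
    """
    s2 = sigma2.to_numpy(dtype=float)
    if len(s2) < 10 and d0_override is None:
        raise ValidationError("moderation requires >= 10 genes")
    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0:
            return ModeratedVariances(0.0, float(np.median(s2)), sigma2.copy())
    else:
        if np.all(s2 <= 0):
            logger.warning("all residual variances are zero; d0 set to infinity")
            return ModeratedVariances(np.inf, 0.0, pd.Series(0.0, index=sigma2.index))
        z = np.log(np.maximum(s2, 1e-300))
        if np.ptp(z) < 1e-12:
            # degenerate: no between-gene spread at all; the common value IS
            # the prior and no log-scale bias correction applies
            return ModeratedVariances(np.inf, float(s2[0]),
                                      pd.Series(float(s2[0]), index=sigma2.index))
        e = z - digamma(df / 2.0) + np.log(df / 2.0)
        emean = e.mean()
        evar = e.var(ddof=1) - polygamma(1, df / 2.0)
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0 = np.inf
            s0 = float(np.exp(emean))
        if np.isinf(d0):
            return ModeratedVariances(d0, s0, pd.Series(s0, index=sigma2.index))
        post = (d0 * s0 + df * s2) / (d0 + df)
        return ModeratedVariances(float(d0), s0, pd.Series(post, index=sigma2.index))
    # finite forced d0
    s0 = float(np.median(s2))
    post = (d0 * s0 + df * s2) / (d0 + df)
    return ModeratedVariances(d0, s0, pd.Series(post, index=sigma2.index))


def run_contrast(fit: LinearFit, contrast: ContrastSpec,
                 moderation: ModeratedVariances) -> pd.DataFrame:
    """Moderated t-test of one contrast: t̃ = c'β̂ / (s̃·√(c'(X'X)⁻¹c)),
    two-sided p from Student t on d0 + d_g degrees of freedom."""
    c = contrast.vector
    if c.size != len(fit.design.coef_names):
        raise ValidationError(
            f"contrast {contrast.name!r} has length {c.size}, "
            f"design has {len(fit.design.coef_names)} coefficients"
        )
    lfc = fit.coefficients.to_numpy() @ c
    unscaled_se = float(np.sqrt(c @ fit.xtx_inv @ c))
    s_tilde = np.sqrt(moderation.posterior.to_numpy(dtype=float))
    df_total = moderation.d0 + fit.df_residual
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (s_tilde * unscaled_se)
    t = np.where(np.isnan(t), 0.0, t)   # 0/0: no effect, no variance
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"log2FC": lfc, "t": t, "p": p, "df": df_total},
        index=fit.coefficients.index,
    )


def standard_contrasts(design: DesignSpec, treatments=("control", "inhibitor")) -> list[ContrastSpec]:
    """The six pairwise stage comparisons: 3v0, 8v0, 8v3 under each arm
    (the shared baseline group serves as 0 dpa for both)."""
    names = design.coef_names
    baseline = names[0]
    tps = sorted({n.split("dpa")[0] for n in names[1:]}, key=float)
    out = []
    for treat in treatments:
        arm = [f"{tp}dpa_{treat}" for tp in tps if f"{tp}dpa_{treat}" in names]
        pairs = [(arm[0], baseline), (arm[-1], baseline)] + \
                [(arm[i + 1], arm[i]) for i in range(len(arm) - 1)]
        for hi, lo in pairs:
            vec = np.zeros(len(names))
            vec[names.index(hi)] = 1.0
            vec[names.index(lo)] = -1.0
            hi_tp = hi.split("dpa")[0]
            lo_tp = lo.split("dpa")[0]
            out.append(ContrastSpec(f"{hi_tp}v{lo_tp}_{treat}", vec))
    # drop duplicates while keeping order (e.g. 3v0 appears once per arm)
    seen = set()
    uniq = []
    for cs in out:
        if cs.name not in seen:
            seen.add(cs.name)
            uniq.append(cs)
    return uniq


def run_all_contrasts(expr: ExpressionMatrix, samples: SampleTable,
                      d0_override: float | None = None) -> dict[str, pd.DataFrame]:
    """Fit, moderate and test the six standard comparisons for one tissue."""
    fit = fit_linear_models(expr, samples)
    mod = moderate_variances(fit.sigma2, fit.df_residual, d0_override)
    return {cs.name: run_contrast(fit, cs, mod)
            for cs in standard_contrasts(fit.design)}


DYNAMIC_COMPARISONS = ("3v0_control", "8v0_control", "8v3_control",
                       "3v0_inhibitor", "8v0_inhibitor", "8v3_inhibitor")


def select_dynamic_genes(results: dict[str, pd.DataFrame],
                         p_threshold: float = 0.05,
                         required: tuple = DYNAMIC_COMPARISONS) -> list[str]:
    """Genes with unadjusted p below threshold in >= 1 of the six comparisons,
    returned in stable (sorted) gene order."""
    missing = [c for c in required if c not in results]
    if missing:
        raise ValidationError(f"missing comparisons: {missing}")
    selected: set = set()
    for name in required:
        df = results[name]
        selected.update(df.index[df["p"] < p_threshold])
    return sorted(selected)
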