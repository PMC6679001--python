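"""Local beat asymmetry and condition comparison statistics.

The local beat asymmetry at flagellar position ``s`` is the absolute value
of the time-averaged curvature angle,

    a(s) = | mean over t of theta(s, t) |,

reported in degrees.  A perfectly symmetric beat averages to zero over full
beat cycles; a static bend (e.g. the hook-shaped asymmetric beat induced by
raised cAMP) shifts the average away from zero.

Condition effects are quantified per position: difference curves
(mean +/- SD across sperm of the within-sperm change, or the difference of
group means for unpaired designs) and pointwise p-values from a two-way
ANOVA (factors condition and flagellar position, sperm as replicates) with
Tukey-HSD contrasts of condition within each position.  Contiguous runs of
p < alpha are reported as significant regions together with the minimum p
inside each region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range, t as t_dist

from .kinematics import CurvatureField

__all__ = [
    "AsymmetryProfile",
    "ConditionComparison",
    "SignificantRegion",
    "asymmetry_profile",
    "difference_curve",
    "pointwise_anova",
    "significant_regions",
]


@dataclass
class AsymmetryProfile:
    """Per-position local beat asymmetry of one sperm (degrees)."""

    s_um: np.ndarray
    a_deg: np.ndarray
    valid: np.ndarray
    n_frames: int
    sperm_id: str = ""
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_um": self.s_um, "a_deg": self.a_deg, "valid": self.valid,
            "sperm_id": self.sperm_id, "condition": self.condition,
        })


@dataclass
class SignificantRegion:
    start_um: float
    end_um: float
    min_p: float


@dataclass
class ConditionComparison:
    """Pointwise condition difference and significance along the flagellum."""

    s_um: np.ndarray
    delta_mean_deg: np.ndarray
    delta_sd_deg: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05
    regions: list[SignificantRegion] = field(default_factory=list)
    paired: bool = True
    anova_table: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_um": self.s_um,
            "delta_mean_deg": self.delta_mean_deg,
            "delta_sd_deg": self.delta_sd_deg,
            "n_A": self.n_a,
            "n_B": self.n_b,
            "p": self.p,
            "significant": self.significant,
        })

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.start_um, r.end_um, r.min_p) for r in self.regions],
            columns=["start_um", "end_um", "min_p"],
        )


def asymmetry_profile(
    field_: CurvatureField,
    sperm_id: str = "",
    condition: str = "",
    min_valid_frac: float = 0.5,
) -> AsymmetryProfile:
    """a(s) = |time-average of the valid curvature angles| in degrees.

    Positions with fewer than ``min_valid_frac`` valid frames are masked.
    The time average should span an integer number of beat cycles (with the
    default 400-frame window at 200 fps any frequency on the 0.5 Hz FFT grid
    fits an integer count).
    """
    n_s, n_t = field_.theta_rad.shape
    if n_t == 0 or n_s == 0:
        raise ValueError("empty curvature field")
    nvalid = field_.valid.sum(axis=1)
    ok = nvalid >= min_valid_frac * n_t
    sums = np.where(field_.valid, field_.theta_rad, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(nvalid > 0, sums / np.maximum(nvalid, 1), np.nan)
    a = np.abs(np.degrees(mean))
    a[~ok] = np.nan
    return AsymmetryProfile(s_um=field_.s_um.copy(), a_deg=a, valid=ok, n_frames=n_t,
                            sperm_id=sperm_id, condition=condition)


def _common_grid(profiles: list[AsymmetryProfile]) -> np.ndarray:
    grids = [p.s_um for p in profiles]
    g0 = grids[0]
    n = min(len(g) for g in grids)
    for g in grids:
        if not np.allclose(g[:n], g0[:n]):
            raise ValueError("profiles are not on a common position grid")
    return g0[:n]


def _stack(profiles: list[AsymmetryProfile], s: np.ndarray) -> np.ndarray:
    n = len(s)
    out = np.full((len(profiles), n), np.nan)
    for i, p in enumerate(profiles):
        a = p.a_deg[:n].copy()
        a[~p.valid[:n]] = np.nan
        out[i] = a
    return out


def difference_curve(
    group_a: list[AsymmetryProfile],
    group_b: list[AsymmetryProfile],
    paired: bool = True,
    alpha: float = 0.05,
) -> ConditionComparison:
    """Per-position difference B - A across sperm.

    Paired mode (the default: the same tethered cells are measured before
    and after stimulation) matches sperm by ``sperm_id`` and reports the
    mean and SD over sperm of the within-sperm difference; unpaired mode
    reports the difference of group means with the pooled SD.  Unmatched ids
    in paired mode fall back to unpaired with a warning.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    s = _common_grid(group_a + group_b)
    if paired:
        ids_a = {p.sperm_id: p for p in group_a}
        ids_b = {p.sperm_id: p for p in group_b}
        common = [i for i in ids_a if i in ids_b]
        if len(common) == len(ids_a) == len(ids_b) and len(common) == len(group_a) == len(group_b):
            aa = _stack([ids_a[i] for i in common], s)
            bb = _stack([ids_b[i] for i in common], s)
            d = bb - aa
            n_pair = np.isfinite(d).sum(axis=0)
            mean = _nanmean(d)
            sd = _nanstd(d)
            comp = ConditionComparison(
                s_um=s, delta_mean_deg=mean, delta_sd_deg=sd,
                n_a=n_pair, n_b=n_pair, p=np.full(len(s), np.nan),
                significant=np.zeros(len(s), dtype=bool), alpha=alpha, paired=True,
            )
            return comp
        warnings.warn("paired comparison requested but sperm_ids do not match; "
                      "falling back to unpaired")
    aa = _stack(group_a, s)
    bb = _stack(group_b, s)
    n_a = np.isfinite(aa).sum(axis=0)
    n_b = np.isfinite(bb).sum(axis=0)
    mean = _nanmean(bb) - _nanmean(aa)
    va, vb = _nanvar(aa), _nanvar(bb)
    dof = np.maximum(n_a + n_b - 2, 1)
    pooled = np.sqrt(((n_a - 1) * va + (n_b - 1) * vb) / dof)
    return ConditionComparison(
        s_um=s, delta_mean_deg=mean, delta_sd_deg=pooled,
        n_a=n_a, n_b=n_b, p=np.full(len(s), np.nan),
        significant=np.zeros(len(s), dtype=bool), alpha=alpha, paired=False,
    )


def _nanmean(x: np.ndarray) -> np.ndarray:
    n = np.isfinite(x).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(x, axis=0)
    return np.where(n >= 1, m, np.nan)


def _nanstd(x: np.ndarray) -> np.ndarray:
    return np.sqrt(_nanvar(x))


def _nanvar(x: np.ndarray) -> np.ndarray:
    n = np.isfinite(x).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = np.nanvar(x, axis=0, ddof=1)
    return np.where(n >= 2, v, np.nan)


def significant_regions(s_um: np.ndarray, p: np.ndarray, alpha: float = 0.05) -> list[SignificantRegion]:
    """Maximal contiguous runs of p < alpha, each with its minimum p."""
    sig = np.asarray(p) < alpha
    regions: list[SignificantRegion] = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            regions.append(SignificantRegion(
                start_um=float(s_um[i]), end_um=float(s_um[j]),
                min_p=float(np.min(p[i : j + 1])),
            ))
            i = j + 1
        else:
            i += 1
    return regions


def pointwise_anova(
    groups: dict[str, list[AsymmetryProfile]],
    alpha: float = 0.05,
    compute_omnibus: bool = True,
) -> ConditionComparison:
    """Two-way ANOVA (condition x position) with per-position Tukey contrasts.

    The asymmetry values of all sperm enter a two-factor linear model with
    condition and flagellar position as crossed factors and sperm as
    replicates.  The pooled within-cell mean square provides the error term;
    at each position, conditions are compared with Tukey's honestly
    significant difference (studentized range with k = number of
    conditions), yielding p(s).  With two conditions the difference curve is
    reported as condition2 - condition1.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two conditions")
    for nm in names:
        if len(groups[nm]) < 2:
            raise ValueError(f"condition {nm!r} has fewer than 2 sperm")
    s = _common_grid([p for nm in names for p in groups[nm]])
    n_s = len(s)
    data = {nm: _stack(groups[nm], s) for nm in names}  # (n_sperm, n_s)

    # pooled within-cell variance over all (condition, position) cells
    sse = 0.0
    df_err = 0
    cell_mean = {nm: _nanmean(data[nm]) for nm in names}
    cell_n = {nm: np.isfinite(data[nm]).sum(axis=0) for nm in names}
    for nm in names:
        x = data[nm]
        resid = x - cell_mean[nm][None, :]
        finite = np.isfinite(resid)
        sse += np.nansum(np.where(finite, resid, 0.0) ** 2)
        df_err += int((cell_n[nm] - 1).clip(min=0).sum())
    deficient = [
        (nm, float(s[j])) for nm in names for j in np.flatnonzero(cell_n[nm] < 2)
    ]
    if deficient:
        nm, pos = deficient[0]
        raise ValueError(f"singular design: condition {nm!r} has < 2 sperm at s = {pos} µm")
    if df_err <= 0 or sse <= 0:
        raise ValueError("degenerate ANOVA: zero residual variance "
                         "(all observations identical within cells)")
    mse = sse / df_err

    k = len(names)
    means = np.stack([cell_mean[nm] for nm in names])  # (k, n_s)
    ns = np.stack([cell_n[nm] for nm in names]).astype(float)
    # Tukey-Kramer: studentized range of all pairwise contrasts per position
    diffs = np.abs(means[:, None, :] - means[None, :, :])
    se = np.sqrt(mse / 2 * (1 / ns[:, None, :] + 1 / ns[None, :, :]))
    with np.errstate(invalid="ignore", divide="ignore"):
        q = diffs / se
    qmax = np.nanmax(q.reshape(k * k, n_s), axis=0)
    if k == 2:
        # the studentized range with k = 2 is sqrt(2)*|t|: use the exact
        # (and much faster) t-distribution tail
        p_vals = 2 * t_dist.sf(qmax / np.sqrt(2.0), df_err)
    else:
        p_vals = studentized_range.sf(qmax, k, df_err)

    sig = p_vals < alpha
    regions = significant_regions(s, p_vals, alpha)

    anova_tab = _omnibus_anova(names, data, s) if compute_omnibus else None

    a, b = names[0], names[-1]
    delta = cell_mean[b] - cell_mean[a]
    # SD of the pointwise difference: pooled across the two (extreme) conditions
    sd = np.sqrt(_nanvar(data[a]) * 0.5 + _nanvar(data[b]) * 0.5)
    return ConditionComparison(
        s_um=s, delta_mean_deg=delta, delta_sd_deg=sd,
        n_a=cell_n[a], n_b=cell_n[b], p=p_vals, significant=sig,
        alpha=alpha, regions=regions, paired=False, anova_table=anova_tab,
    )


def _omnibus_anova(names, data, s) -> pd.DataFrame:
    """Omnibus two-way ANOVA table (statsmodels OLS, type II)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    for nm in names:
        x = data[nm]
        for i in range(x.shape[0]):
            finite = np.isfinite(x[i])
            rows.append(pd.DataFrame({
                "a": x[i, finite], "condition": nm, "position": s[finite],
            }))
    df = pd.concat(rows, ignore_index=True)
    model = smf.ols("a ~ C(condition) * C(position)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)
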