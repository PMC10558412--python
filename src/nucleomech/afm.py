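"""AFM approach-curve analysis: contact point, Hertz fit, aggregation.

Each approach curve records force versus piezo displacement. Before
contact the cantilever reads a flat (noisy) baseline; after the contact
point ``z_c`` the force rises as the Hertzian sphere-on-halfspace law
F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2) with indentation depth
``delta = z - z_c``. Per-nucleus stiffness maps are built from thousands
of curves (PeakForce-style acquisition), so per-curve estimates are
aggregated into a mean ± SD per nucleus and a heterogeneity (CV) summary
per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "AfmCurve",
    "NucleusStiffness",
    "find_contact_point",
    "fit_curve_modulus",
    "aggregate_nucleus",
    "population_summary",
    "HertzContactModel",
]


@dataclass(frozen=True)
class AfmCurve:
    """One approach force–distance curve.

    z_nm increases toward the sample; force_nN is the deflection-converted
    force. ``tip_radius_nm`` must be supplied by the user (cantilever
    geometry is instrument metadata, never inferred).
    """

    z_nm: np.ndarray
    force_nN: np.ndarray
    tip_radius_nm: float
    max_force_nN: float = float("nan")

    def __post_init__(self) -> None:
        z = np.asarray(self.z_nm, dtype=float)
        f = np.asarray(self.force_nN, dtype=float)
        if z.ndim != 1 or z.shape != f.shape:
            raise ValueError("z_nm and force_nN must be 1-D and equal length")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z_nm must be strictly increasing over the approach")
        if not np.all(np.isfinite(f)):
            raise ValueError("forces must be finite")
        if not self.tip_radius_nm > 0:
            raise ValueError("tip_radius_nm must be > 0")
        object.__setattr__(self, "z_nm", z)
        object.__setattr__(self, "force_nN", f)


@dataclass
class NucleusStiffness:
    """Per-nucleus aggregate of per-curve Young's modulus estimates."""

    E_mean_pa: float
    E_sd_pa: float
    n_curves: int
    condition: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)


def _hertz_coef_nN_per_nm15(E_pa: float, R_nm: float, nu: float) -> float:
    """Hertz prefactor k such that F_nN = k * delta_nm**1.5."""
    # F[N] = (4/3) E/(1-nu^2) sqrt(R[m]) delta[m]^1.5
    #      = (4/3) E/(1-nu^2) sqrt(R_nm*1e-9) * (1e-9)^1.5 * delta_nm^1.5
    return (4.0 / 3.0) * (E_pa / (1.0 - nu**2)) * np.sqrt(R_nm * 1e-9) * (1e-9) ** 1.5 * 1e9


def find_contact_point(curve: AfmCurve, min_baseline_samples: int = 50) -> tuple[float, dict]:
    """Locate the contact point by joint piecewise fitting.

    For every candidate index the curve is modelled as (flat baseline
    before, Hertzian rise after); the candidate minimising the total
    residual sum of squares is returned, with residual diagnostics.
    """
    z, f = curve.z_nm, curve.force_nN
    n = len(z)
    if n < min_baseline_samples + 10:
        raise ValueError("curve too short for contact-point detection")
    # require an actual baseline: the first samples must not already be rising
    cum_f = np.concatenate([[0.0], np.cumsum(f)])
    cum_f2 = np.concatenate([[0.0], np.cumsum(f**2)])
    best = (np.inf, None)
    # candidate contact indices leave >= min_baseline_samples before and
    # >= 10 samples after
    for i in range(min_baseline_samples, n - 10):
        zc = z[i]
        base = f[:i].mean() if i else 0.0
        rss_base = cum_f2[i] - cum_f[i] ** 2 / i
        x = (z[i:] - zc) ** 1.5
        y = f[i:] - base
        denom = float(np.dot(x, x))
        if denom <= 0:
            continue
        k = float(np.dot(x, y) / denom)
        if k < 0:
            k = 0.0
        rss_post = float(np.sum((y - k * x) ** 2))
        rss = rss_base + rss_post
        if rss < best[0]:
            best = (rss, i)
    if best[1] is None:
        raise ValueError("no baseline region found")
    i = best[1]
    # reject curves with no genuine flat region: the pre-contact segment of
    # a monotone-rising curve drifts by a noticeable fraction of the range
    base_seg = f[:i]
    drift = abs(float(base_seg[-10:].mean() - base_seg[:10].mean()))
    if drift > 0.03 * float(np.ptp(f)):
        raise ValueError("no baseline region: curve rises from the first sample")
    diagnostics = {"rss": best[0], "baseline_nN": float(f[:i].mean()), "index": i}
    return float(z[i]), diagnostics


def fit_curve_modulus(
    curve: AfmCurve,
    z_contact_nm: float,
    nu: float = 0.5,
    fit_window: tuple[float, float] = (0.10, 0.90),
    min_depth_nm: float = 20.0,
) -> tuple[float, dict]:
    """Least-squares Hertz fit of Young's modulus over the post-contact range.

    The fit window keeps forces between ``fit_window`` fractions of the
    post-contact maximum, avoiding baseline noise and deep-substrate
    effects. Returns ``(E_pa, diagnostics)``; diagnostics carry flags for
    shallow windows or non-positive fits.
    """
    z, f = curve.z_nm, curve.force_nN
    post = z > z_contact_nm
    if not np.any(post):
        raise ValueError("no post-contact data")
    depth = z[post] - z_contact_nm
    force = f[post]
    if depth[-1] < min_depth_nm:
        raise ValueError(f"post-contact depth {depth[-1]:.1f} nm < {min_depth_nm} nm")
    fmax = float(force.max())
    lo, hi = fit_window
    sel = (force >= lo * fmax) & (force <= hi * fmax)
    flags: list[str] = []
    if np.sum(sel) < 10:
        sel = np.ones_like(force, dtype=bool)
        flags.append("narrow_window")
    if depth[sel][-1] - depth[sel][0] <= min_depth_nm * 1.5:
        flags.append("wide_confidence")
    x = depth[sel] ** 1.5
    y = force[sel]
    k = float(np.dot(x, y) / np.dot(x, x))
    unit = _hertz_coef_nN_per_nm15(1.0, curve.tip_radius_nm, nu)
    E = k / unit
    rss = float(np.sum((y - k * x) ** 2))
    rel_resid = float(np.sqrt(rss / np.sum(y**2))) if np.any(y) else float("nan")
    if E <= 0:
        flags.append("nonpositive_E")
    return E, {"rss": rss, "rel_resid": rel_resid, "n": int(np.sum(sel)), "flags": tuple(flags)}


def aggregate_nucleus(
    curve_estimates,
    min_curves: int = 4000,
    condition: str = "",
) -> NucleusStiffness:
    """Mean ± SD of per-curve E for one nucleus.

    PeakForce-style maps supply thousands of curves per nucleus; nuclei
    with fewer than ``min_curves`` estimates are kept but flagged
    ``below_minimum`` rather than dropped.
    """
    est = np.asarray(list(curve_estimates), dtype=float)
    if est.size == 0:
        raise ValueError("no curve estimates to aggregate")
    flags: list[str] = []
    if est.size < min_curves:
        flags.append("below_minimum")
    sd = float(est.std(ddof=1)) if est.size > 1 else float("nan")
    return NucleusStiffness(
        E_mean_pa=float(est.mean()),
        E_sd_pa=sd,
        n_curves=int(est.size),
        condition=condition,
        flags=tuple(flags),
    )


def population_summary(nuclei) -> pd.DataFrame:
    """Per-condition mean, SD and coefficient of variation of nucleus
    stiffness; higher CV marks a more mechanically heterogeneous population.
    """
    rows = [
        {"condition": n.condition, "E_mean_pa": n.E_mean_pa} for n in nuclei
    ]
    if not rows:
        raise ValueError("at least one nucleus required")
    df = pd.DataFrame(rows)
    out = []
    for cond, grp in df.groupby("condition", sort=True):
        vals = grp["E_mean_pa"].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        cv = sd / mean if len(vals) > 1 and mean != 0 else float("nan")
        out.append(
            {"condition": cond, "n_nuclei": len(vals), "E_mean_pa": mean, "E_sd_pa": sd, "E_cv": cv}
        )
    return pd.DataFrame(out)


class HertzContactModel(BaseEstimator):
    """Estimator fitting Young's modulus to AFM approach curves.

    ``fit`` accepts one :class:`AfmCurve` or a list of curves (one
    nucleus); the contact point of each curve is co-estimated, absorbing
    any uniform z-offset.

    Attributes
    ----------
    E_pa_ : ndarray
        Per-curve Young's modulus estimates (outlier-rejected fits are NaN).
    z_contact_nm_ : ndarray
        Per-curve contact points.
    nucleus_ : NucleusStiffness
        Aggregate over the accepted per-curve estimates.
    """

    def __init__(
        self,
        nu: float = 0.5,
        fit_window: tuple[float, float] = (0.10, 0.90),
        max_rel_resid: float = 0.20,
        min_curves: int = 4000,
        condition: str = "",
    ):
        self.nu = nu
        self.fit_window = fit_window
        self.max_rel_resid = max_rel_resid
        self.min_curves = min_curves
        self.condition = condition

    def fit(self, X, y=None) -> "HertzContactModel":
        curves = [X] if isinstance(X, AfmCurve) else list(X)
        if not curves:
            raise ValueError("no curves provided")
        E = np.full(len(curves), np.nan)
        zc = np.full(len(curves), np.nan)
        for i, c in enumerate(curves):
            z_contact, _ = find_contact_point(c)
            e, diag = fit_curve_modulus(c, z_contact, nu=self.nu, fit_window=self.fit_window)
            zc[i] = z_contact
            # per-curve outlier rejection on relative residual
            if e > 0 and diag["rel_resid"] <= self.max_rel_resid:
                E[i] = e
        self.E_pa_ = E
        self.z_contact_nm_ = zc
        accepted = E[np.isfinite(E)]
        if accepted.size == 0:
            raise ValueError("all curve fits rejected")
        self.nucleus_ = aggregate_nucleus(
            accepted, min_curves=self.min_curves, condition=self.condition
        )
        return self
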