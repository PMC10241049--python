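"""Monomer-profile reconstruction from aggregate-contaminated SAS data.

Two reconstructions are provided.  The *first* method takes the high-q
monomer estimate I_1H(q) = r_1 I(q) (valid because monomer and aggregates
share the same local structure, so their normalized profiles coincide at
high q), anchors the forward intensity at

    I_1(0) = I(0) r_1 M_1 / sum_j r_j M_j,

and bridges the two with a Guinier curve joined smoothly at a connection
point q_c.  With more than ~10% aggregates the joint is forced outside the
Guinier region and R_g1 comes out biased high.

The *improved* method divides the measured profile by the mixture factor

    S(q) = sum_j r_j [1 + beta(q) (T_j(q) - 1)]

of the decoupling aggregate model before connecting, i.e.
I_1H(q) = r_1 I(q) / S(q), which extrapolates correctly into the Guinier
region.  R_g1 enters S(q) through T_j and beta, so the reconstruction is
iterated from the first-method estimate until R_g1 is self-consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .auc_model import (
    SolventConditions,
    assign_association_numbers,
    axial_ratio_from_friction,
)
from .sas_io import ScatteringProfile, SpeciesDistribution
from .scattering_models import AggregateModel, build_aggregate_model

logger = logging.getLogger(__name__)

__all__ = [
    "GuinierFit",
    "ConnectionResult",
    "MonomerResult",
    "extrapolate_forward",
    "highq_monomer_first",
    "forward_intensity_monomer",
    "guinier_connect",
    "mixture_factor",
    "first_aucsas",
    "improved_aucsas",
]

#: Upper limit of the Guinier approximation, q * R_g <= 1.3.
GUINIER_CAP = 1.3


@dataclass(frozen=True)
class GuinierFit:
    """Result of a weighted Guinier fit ln I = ln I(0) - q^2 R_g^2 / 3."""

    i_zero: float
    i_zero_sd: float
    rg: float
    rg_sd: float
    n_points: int
    q_window: tuple[float, float]


@dataclass
class ConnectionResult:
    """Smooth Guinier joint between I_1(0) and a high-q monomer estimate."""

    rg1: float
    rg1_sd: float
    q_connect: float
    profile: ScatteringProfile
    joint_metric: float
    scan_rg: float


@dataclass
class MonomerResult:
    """Reconstructed monomer profile and its scalar descriptors.

    ``profile`` holds the absolute monomer intensity I_1(q) (1/cm) with
    ``concentration`` set to the monomer concentration c_1 = r_1 c;
    ``i1_zero`` is the concentration-normalized forward intensity
    I_1(0)/c_1 in cm^2/mg.
    """

    profile: ScatteringProfile
    rg1: float
    rg1_sd: float
    I1_zero: float
    I1_zero_sd: float
    i1_zero: float
    i1_zero_sd: float
    q_connect: float
    method: str
    iterations: int
    distribution: SpeciesDistribution | None = None
    mixture_factor: np.ndarray | None = None
    guinier_total: GuinierFit | None = None
    warnings: list[str] = field(default_factory=list)
    dmax: float | None = None

    @property
    def normalized_profile(self) -> ScatteringProfile:
        """i_1(q) = I_1(q)/c_1, cm^2/mg."""
        return self.profile.to_normalized()


def _weighted_linfit(
    x: np.ndarray, y: np.ndarray, sy: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """WLS fit y = a + b x; returns (a, b, covariance)."""
    w = 1.0 / np.maximum(sy, 1e-12) ** 2
    sw, sx, sxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    sy_, sxy = (w * y).sum(), (w * x * y).sum()
    det = sw * sxx - sx * sx
    if det <= 0:
        raise ValueError("degenerate design in weighted linear fit")
    a = (sxx * sy_ - sx * sxy) / det
    b = (sw * sxy - sx * sy_) / det
    cov = np.array([[sxx, -sx], [-sx, sw]]) / det
    return a, b, cov


def extrapolate_forward(
    profile: ScatteringProfile,
    rg_hint: float | None = None,
    cap: float = GUINIER_CAP,
    min_points: int = 5,
    max_iter: int = 30,
) -> GuinierFit:
    """Guinier extrapolation of a profile to q = 0.

    Weighted linear fit of ln I versus q^2 restricted to q * R_g <= ``cap``.
    With ``rg_hint`` the window is fixed by the hint; otherwise the window
    is determined self-consistently from the fit's own apparent R_g.  For a
    mixture the returned R_g is the apparent ensemble value, which exceeds
    the monomer R_g when aggregates are present.
    """
    pos = (profile.intensity > 0) & (profile.sigma >= 0)
    q = profile.q[pos]
    y = np.log(profile.intensity[pos])
    sy = profile.sigma[pos] / profile.intensity[pos]
    x = q * q
    if rg_hint is not None:
        mask = q * rg_hint <= cap
        if mask.sum() < min_points:
            raise ValueError(
                f"only {int(mask.sum())} points with q*rg_hint <= {cap}; "
                f"need {min_points}"
            )
        windows = [mask]
    else:
        first = np.zeros_like(q, dtype=bool)
        first[: max(8, len(q) // 10)] = True
        mask = first
        for _ in range(max_iter):
            a, b, _ = _weighted_linfit(x[mask], y[mask], sy[mask])
            if b >= 0:
                # noise-flat start: widen until a decaying slope appears
                if mask.all():
                    break
                wider = np.zeros_like(mask)
                wider[: min(len(q), 2 * int(mask.sum()))] = True
                mask = wider
                continue
            rg = np.sqrt(-3.0 * b)
            new = q * rg <= cap
            if new.sum() < min_points:
                new = first
            if np.array_equal(new, mask):
                break
            mask = new
    a, b, cov = _weighted_linfit(x[mask], y[mask], sy[mask])
    if b >= 0:
        raise ValueError("non-negative Guinier slope; no decaying signal")
    rg = float(np.sqrt(-3.0 * b))
    rg_sd = float(np.sqrt(cov[1, 1]) * 3.0 / (2.0 * rg))
    i0 = float(np.exp(a))
    return GuinierFit(
        i_zero=i0,
        i_zero_sd=i0 * float(np.sqrt(cov[0, 0])),
        rg=rg,
        rg_sd=rg_sd,
        n_points=int(mask.sum()),
        q_window=(float(q[mask].min()), float(q[mask].max())),
    )


def highq_monomer_first(profile: ScatteringProfile, r1: float) -> ScatteringProfile:
    """First-method high-q monomer estimate, I_1H(q) = r_1 I(q).

    Valid as a monomer profile only at sufficiently high q (q R_g1 > 3);
    at lower q it retains the aggregate excess.
    """
    if not 0 < r1 <= 1:
        raise ValueError("monomer weight fraction must be in (0, 1]")
    return profile.scaled(r1)


def forward_intensity_monomer(
    i0_total: float,
    distribution: SpeciesDistribution,
    i0_total_sd: float = 0.0,
) -> tuple[float, float]:
    """Monomer forward intensity I_1(0) from I(0) and the AUC table.

        I_1(0) = I(0) r_1 M_1 / sum_j r_j M_j

    (forward intensity of each species is proportional to c_j M_j).  The
    error is propagated linearly from the I(0) fit error.
    """
    if i0_total <= 0:
        raise ValueError("I(0) must be positive")
    if not distribution.has_masses:
        raise ValueError("all species need molar masses; run "
                         "assign_association_numbers first")
    r1 = distribution.monomer.weight_fraction
    m1 = distribution.monomer.molar_mass
    denom = sum(sp.weight_fraction * sp.molar_mass for sp in distribution.species)
    factor = r1 * m1 / denom
    return i0_total * factor, i0_total_sd * factor


def mixture_factor(
    q: np.ndarray, distribution: SpeciesDistribution, model: AggregateModel
) -> np.ndarray:
    """Mixture factor S(q) = sum_j r_j [1 + beta(q) (T_j(q) - 1)].

    S(0) = sum_j r_j j and S -> 1 at high q, so dividing the measured
    profile by S removes the aggregate excess at all q.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != model.q.shape or not np.allclose(q, model.q):
        raise ValueError("q grid does not match the aggregate model grid")
    if not distribution.has_association_numbers:
        raise ValueError("species need association numbers")
    s = np.zeros_like(q)
    for sp in distribution.species:
        j = sp.association_number
        tj = (
            np.ones_like(q)
            if j == 1
            else model.t_factors[j]
        )
        s += sp.weight_fraction * (1.0 + model.beta * (tj - 1.0))
    return s


def _local_log_fits(
    x: np.ndarray, y: np.ndarray, sy: np.ndarray, half_window: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Windowed WLS of ln I vs q^2 around every point.

    Returns smoothed values, their standard errors, local slopes and slope
    standard errors.  Used to compare value and derivative of the data
    against a Guinier candidate without amplifying point noise.
    """
    n = len(x)
    val = np.empty(n)
    val_se = np.empty(n)
    slope = np.empty(n)
    slope_se = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        if hi - lo < 3:
            lo, hi = max(0, hi - 3), min(n, lo + 3)
        xs, ys, ss = x[lo:hi], y[lo:hi], sy[lo:hi]
        a, b, cov = _weighted_linfit(xs - x[i], ys, ss)
        val[i], slope[i] = a, b
        val_se[i] = np.sqrt(cov[0, 0])
        slope_se[i] = np.sqrt(cov[1, 1])
    return val, val_se, slope, slope_se


def guinier_connect(
    i1h: ScatteringProfile,
    i1_zero: float,
    i1_zero_sd: float = 0.0,
    validity_limit: float = GUINIER_CAP,
    qc_cap: float = 3.0,
    joint_tol: float = 0.05,
    rg_scan: tuple[float, float] | None = None,
    slope_window: int = 5,
    consecutive: int = 3,
) -> ConnectionResult:
    """Connect I_1(0) to a high-q monomer estimate with a Guinier bridge.

    The Guinier curve G(q) = I_1(0) exp(-q^2 R_g1^2/3) is an adjustable
    one-parameter family; requiring it to pass through the locally smoothed
    data at a candidate connection point q_c fixes

        R_g1^2(q_c) = 3 [ln I_1(0) - ln i1h(q_c)] / q_c^2,

    so a smooth joint additionally needs only the local slope of ln i1h
    versus q^2 to agree with -R_g1^2/3.  q_c is the smallest data point
    whose relative slope discontinuity falls below ``joint_tol`` (widened
    where the slope itself is too noisy to measure); the discontinuity at
    the chosen joint is reported as the metric.  The returned profile
    follows the Guinier curve below q_c and the data above, and the final
    R_g1 and its standard deviation come from a weighted Guinier refit of
    that hybrid profile over q R_g1 <= ``validity_limit``.

    Raises ``ValueError`` when no candidate achieves an acceptable joint,
    which signals mutually inconsistent I_1(0), r_1 and I(q).
    """
    if i1_zero <= 0:
        raise ValueError("I_1(0) must be positive")
    pos = i1h.intensity > 0
    q = i1h.q[pos]
    if len(q) < 7:
        raise ValueError("too few positive intensities to connect")
    x = q * q
    y = np.log(i1h.intensity[pos])
    sy = i1h.sigma[pos] / i1h.intensity[pos]
    val, val_se, slope, slope_se = _local_log_fits(
        x, y, sy, half_window=slope_window
    )
    ln_i0 = np.log(i1_zero)

    # Candidate connection points: at q_c the Guinier curve through I_1(0)
    # that matches the (smoothed) data value exactly has
    # R_g^2 = 3 [ln I_1(0) - ln i1h(q_c)] / q_c^2; the joint is smooth when
    # the local slope of ln i1h vs q^2 also agrees with -R_g^2/3.
    with np.errstate(invalid="ignore"):
        rg2 = 3.0 * (ln_i0 - val) / x
    candidate = rg2 > 0
    rg_cand = np.sqrt(np.where(candidate, rg2, np.nan))
    if rg_scan is not None:
        candidate &= (rg_cand >= rg_scan[0]) & (rg_cand <= rg_scan[1])
    candidate &= q * np.where(candidate, rg_cand, np.inf) <= qc_cap
    if not candidate.any():
        raise ValueError(
            "no connection candidate: I_1H never falls below the Guinier "
            "curve anchored at I_1(0)"
        )
    # relative slope discontinuity, noise-widened acceptance tolerance;
    # a joint can only be accepted where the local slope is measurable at
    # all (otherwise the lowest, leverage-free points would always "agree")
    dslope = np.abs(slope + rg2 / 3.0) * 3.0 / np.abs(rg2)
    slope_se_rel = slope_se * 3.0 / np.abs(rg2)
    tol = np.maximum(joint_tol, 2.0 * slope_se_rel)
    ok = candidate & (dslope <= tol) & (slope_se_rel <= 5.0 * joint_tol)
    # demand a short run of agreeing points so that a single noise
    # fluctuation in the local slope cannot fake a smooth joint
    run = max(1, consecutive)
    if run > 1 and len(ok) >= run:
        consec = ok.copy()
        for k in range(1, run):
            consec[:-k] &= ok[k:]
        consec[-(run - 1):] = False
        ok = consec
    if ok.any():
        idx = int(np.argmax(ok))  # smallest q that joins smoothly
    else:
        masked = np.where(candidate, dslope, np.inf)
        idx = int(np.argmin(masked))
    metric = float(dslope[idx])
    if not np.isfinite(metric) or metric > 1.0:
        raise ValueError(
            f"no smooth Guinier joint found (best slope discontinuity "
            f"{metric:.3g}); inputs are mutually inconsistent"
        )
    qc = float(q[idx])
    rg_star = float(rg_cand[idx])

    # hybrid profile: Guinier below q_c, data above
    rel_sd = max(i1_zero_sd / i1_zero, 1e-4)
    low = i1h.q < qc
    guinier_part = i1_zero * np.exp(-(i1h.q**2) * rg_star**2 / 3.0)
    intensity = np.where(low, guinier_part, i1h.intensity)
    sigma = np.where(low, guinier_part * rel_sd, i1h.sigma)
    hybrid = ScatteringProfile(
        q=i1h.q.copy(),
        intensity=intensity,
        sigma=sigma,
        concentration=i1h.concentration,
        normalized=i1h.normalized,
    )
    # final weighted Guinier refit of the connected profile
    rg1, rg1_sd = rg_star, float("nan")
    for _ in range(3):
        try:
            refit = extrapolate_forward(hybrid, rg_hint=rg1, cap=validity_limit)
        except ValueError:
            break
        rg1_sd = refit.rg_sd
        if abs(refit.rg - rg1) / rg1 < 1e-6:
            rg1 = refit.rg
            break
        rg1 = refit.rg
    return ConnectionResult(
        rg1=rg1,
        rg1_sd=rg1_sd,
        q_connect=qc,
        profile=hybrid,
        joint_metric=metric,
        scan_rg=rg_star,
    )


def _prepare_distribution(
    distribution: SpeciesDistribution, solvent: SolventConditions | None
) -> SpeciesDistribution:
    if distribution.has_masses and distribution.has_association_numbers:
        return distribution
    if solvent is None:
        raise ValueError(
            "species lack molar masses / association numbers and no "
            "SolventConditions were given to derive them"
        )
    return assign_association_numbers(distribution, solvent)


def first_aucsas(
    profile: ScatteringProfile,
    distribution: SpeciesDistribution,
    solvent: SolventConditions | None = None,
    validity_limit: float = GUINIER_CAP,
) -> MonomerResult:
    """First-version reconstruction: r_1 scaling plus Guinier connection.

    Pipeline: Guinier extrapolation of the total profile -> I(0);
    AUC-weighted forward intensity -> I_1(0); I_1H = r_1 I(q);
    smooth Guinier joint -> (R_g1, q_c, I_1(q)).
    """
    if profile.concentration is None or profile.concentration <= 0:
        raise ValueError("profile needs a positive concentration")
    if profile.normalized:
        raise ValueError("expected an absolute-intensity profile")
    distribution = _prepare_distribution(distribution, solvent)
    notes: list[str] = []
    ra = distribution.aggregate_fraction
    if ra > 0.1:
        notes.append(
            f"r_a = {ra:.2f} > 0.1: the first method is known to bias R_g1 "
            "high; prefer the improved method"
        )
    total_fit = extrapolate_forward(profile)
    I1_zero, I1_zero_sd = forward_intensity_monomer(
        total_fit.i_zero, distribution, total_fit.i_zero_sd
    )
    r1 = distribution.monomer.weight_fraction
    i1h = highq_monomer_first(profile, r1)
    conn = guinier_connect(
        i1h, I1_zero, I1_zero_sd, validity_limit=validity_limit
    )
    if conn.q_connect * conn.rg1 > validity_limit:
        notes.append(
            f"connection point q_c R_g1 = {conn.q_connect * conn.rg1:.2f} "
            f"lies outside the Guinier region (limit {validity_limit})"
        )
    c1 = r1 * profile.concentration
    out_profile = conn.profile
    out_profile.concentration = c1
    return MonomerResult(
        profile=out_profile,
        rg1=conn.rg1,
        rg1_sd=conn.rg1_sd,
        I1_zero=I1_zero,
        I1_zero_sd=I1_zero_sd,
        i1_zero=I1_zero / c1,
        i1_zero_sd=I1_zero_sd / c1,
        q_connect=conn.q_connect,
        method="first",
        iterations=1,
        distribution=distribution,
        guinier_total=total_fit,
        warnings=notes,
    )


def improved_aucsas(
    profile: ScatteringProfile,
    distribution: SpeciesDistribution,
    shape_p: float | None = None,
    solvent: SolventConditions | None = None,
    hydration: float = 0.3,
    max_iter: int = 20,
    tol: float = 1e-3,
    validity_limit: float = GUINIER_CAP,
    neighbor_distance: float | None = None,
) -> MonomerResult:
    """Improved reconstruction: divide by the aggregate mixture factor.

    Starting from the first-method R_g1, iterates

        S(q) with D = 2 R_g1, r = R_g1-matched ellipsoid of ratio p
        I_1H(q) = r_1 I(q) / S(q)
        Guinier joint with I_1(0)  ->  new R_g1

    until |dR_g1|/R_g1 < ``tol`` or ``max_iter``.  ``shape_p`` defaults to
    the Perrin inversion of the distribution's frictional ratio with the
    given ``hydration``.
    """
    distribution = _prepare_distribution(distribution, solvent)
    if shape_p is None:
        shape_p = axial_ratio_from_friction(
            distribution.friction_ratio, hydration, solvent
        )
    first = first_aucsas(
        profile, distribution, validity_limit=validity_limit
    )
    notes: list[str] = []
    ra = distribution.aggregate_fraction
    if ra > 0.2:
        notes.append(
            f"r_a = {ra:.2f} exceeds the 0.2 applicability prerequisite"
        )
    total_fit = first.guinier_total
    I1_zero, I1_zero_sd = first.I1_zero, first.I1_zero_sd
    r1 = distribution.monomer.weight_fraction
    js = [sp.association_number for sp in distribution.species]
    rg = first.rg1
    conn = None
    s_factor = None
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        model = build_aggregate_model(
            profile.q, js, rg, shape_p, neighbor_distance=neighbor_distance
        )
        s_factor = mixture_factor(profile.q, distribution, model)
        i1h = ScatteringProfile(
            q=profile.q.copy(),
            intensity=r1 * profile.intensity / s_factor,
            sigma=r1 * profile.sigma / s_factor,
            concentration=profile.concentration,
        )
        conn = guinier_connect(
            i1h, I1_zero, I1_zero_sd, validity_limit=validity_limit
        )
        drel = abs(conn.rg1 - rg) / rg
        rg = conn.rg1
        if drel < tol:
            converged = True
            break
    if not converged:
        notes.append(
            f"R_g1 iteration did not converge to {tol:g} within "
            f"{max_iter} iterations"
        )
    if conn.q_connect * rg > validity_limit:
        notes.append(
            f"connection point q_c R_g1 = {conn.q_connect * rg:.2f} lies "
            f"outside the Guinier region (limit {validity_limit})"
        )
    c1 = r1 * profile.concentration
    out_profile = conn.profile
    out_profile.concentration = c1
    return MonomerResult(
        profile=out_profile,
        rg1=rg,
        rg1_sd=conn.rg1_sd,
        I1_zero=I1_zero,
        I1_zero_sd=I1_zero_sd,
        i1_zero=I1_zero / c1,
        i1_zero_sd=I1_zero_sd / c1,
        q_connect=conn.q_connect,
        method="improved",
        iterations=iterations,
        distribution=distribution,
        mixture_factor=s_factor,
        guinier_total=total_fit,
        warnings=notes,
    )
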