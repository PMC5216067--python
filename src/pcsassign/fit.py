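"""Δχ-tensor fitting from assigned PCSs.

One tensor is fit per (tag site, lanthanide) group by weighted nonlinear
least squares, pooling the PCSs measured on all isotopically labeled subunits
of that group and assuming a single metal position for the group.  The
objective is

    Σ_i [ (observed_i − predicted_i) / tolerance_i ]²

so ¹H and ¹³C records are weighted by their inverse squared measurement
precisions (0.008 and 0.05 ppm by default).

Because the PCS is linear in the five independent components of the traceless
χ tensor once the metal position is fixed (see :mod:`pcsassign.tensor`), the
fit is solved by variable projection: an outer 3-parameter nonlinear search
over the metal position with, at every trial position, an exact inner weighted
linear solve for the tensor components.  The outer search is multi-started
from jittered positions around the supplied initial metal guess (typically the
tagged residue's Cβ).  Results are reported in the unique tensor
representation (UTR).

Fit quality is summarized by the Q factor,

    Q = rms(observed − calculated) / rms(observed),

and by the slope m and intercept y0 of the ordinary least-squares line of
observed versus calculated PCSs.  Parameter uncertainties come from a Monte
Carlo protocol: refitting on random subsets with a fraction of the PCSs
omitted (default 100 samples, 20% omission) and taking per-parameter standard
deviations over the UTR-reduced refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tensor import PCS_PREFACTOR, ChiTensor, chi_to_tensor, pcs_forward

__all__ = [
    "FitResult",
    "FitOptions",
    "fit_tensor",
    "q_factor",
    "regression_stats",
    "monte_carlo_errors",
    "leave_out_refit",
]

MIN_RECORDS = 8  # free parameters: dchi_ax, dchi_rh, 3 orientation, metal xyz


@dataclass
class FitOptions:
    """Tunables of the tensor fit.

    ``initial_metal`` should be the tagged residue's side-chain terminus (Cβ
    works well); when ``None`` the centroid of the evaluation points is used.
    ``n_starts`` jittered starting metal positions (uniform in a ball of
    radius ``jitter`` Å) are tried in addition to the unjittered guess.
    """

    initial_metal: np.ndarray | None = None
    n_starts: int = 16
    jitter: float = 5.0
    fix_metal: bool = False
    seed: int = 0
    ftol: float = 1e-12
    xtol: float = 1e-12
    min_r: float = 1.0
    # Optional soft restraint keeping the metal within the covalent reach of
    # the tagged side chain: zero inside ``prior_radius`` Å of
    # ``prior_center``, then a residual of ``prior_weight`` per Å.  Useful
    # when few PCSs are available (early assignment iterations).
    prior_center: np.ndarray | None = None
    prior_radius: float = 12.0
    prior_weight: float = 10.0


@dataclass
class FitResult:
    tensor: ChiTensor
    records: list  # fitted records, same order as residuals
    residuals: np.ndarray  # observed - calculated, ppm
    q: float
    slope: float
    intercept: float
    objective: float
    n_starts_tried: int = 1
    mc_std: dict | None = None


def q_factor(observed, calculated) -> float:
    """Q = rms(observed − calculated) / rms(observed)."""
    obs = np.asarray(observed, float)
    calc = np.asarray(calculated, float)
    if obs.shape != calc.shape or obs.size == 0:
        raise ValueError("observed and calculated must be equal-length, non-empty")
    denom = np.sqrt(np.mean(obs**2))
    if denom == 0:
        raise ValueError("Q factor undefined: all observed values are zero")
    return float(np.sqrt(np.mean((obs - calc) ** 2)) / denom)


def regression_stats(observed, calculated):
    """Ordinary least-squares line observed = m·calculated + y0 → (m, y0)."""
    obs = np.asarray(observed, float)
    calc = np.asarray(calculated, float)
    if obs.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(calc) == 0:
        raise ValueError("degenerate regression: all calculated values equal")
    m, y0 = np.polyfit(calc, obs, 1)
    return float(m), float(y0)


# ---------------------------------------------------------------------------


def _evaluation_points(records, methyls):
    """(n, 3) evaluation points, observed values and weights for fittable
    records (measured, assigned)."""
    by_id = {m.methyl_id: m for m in methyls}
    pts, obs, w, kept = [], [], [], []
    for r in records:
        if r.value is None or r.methyl_id is None:
            continue
        m = by_id.get(r.methyl_id)
        if m is None:
            raise KeyError(f"record references unknown methyl {r.methyl_id}")
        pts.append(m.proton_position if r.nucleus == "H" else m.carbon_position)
        obs.append(r.value)
        w.append(1.0 / r.tolerance)
        kept.append(r)
    return np.array(pts, float), np.array(obs), np.array(w), kept


def _design_matrix(points, metal):
    """Rows map the 5 free χ components (χxx, χyy, χxy, χxz, χyz) to ppm."""
    d = points - metal
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    r5 = (x * x + y * y + z * z) ** 2.5
    pref = PCS_PREFACTOR / r5
    return np.column_stack(
        [x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    ) * pref[:, None]


def _chi_from_components(c):
    cxx, cyy, cxy, cxz, cyz = c
    return np.array([[cxx, cxy, cxz], [cxy, cyy, cyz], [cxz, cyz, -cxx - cyy]])


def _solve_at_metal(metal, points, obs, w):
    """Inner linear solve; returns (chi5, weighted residual vector)."""
    a = _design_matrix(points, metal) * w[:, None]
    b = obs * w
    chi5, *_ = np.linalg.lstsq(a, b, rcond=None)
    return chi5, b - a @ chi5


def tensor_at_metal(records, methyls, metal, min_r: float = 1.0) -> ChiTensor | None:
    """Exact weighted linear solve for the χ components at a fixed metal
    position (the PCS is linear in χ once the metal is pinned).

    Needs ≥5 measured, assigned records; returns ``None`` when the metal sits
    within ``min_r`` Å of an evaluation point or data are insufficient.
    """
    points, obs, w, kept = _evaluation_points(records, methyls)
    if len(kept) < 5:
        return None
    metal = np.asarray(metal, float)
    d = points - metal
    if np.min(np.einsum("ij,ij->i", d, d)) < min_r**2:
        return None
    chi5, _ = _solve_at_metal(metal, points, obs, w)
    return chi_to_tensor(_chi_from_components(chi5), metal)


def fit_tensor(records, methyls, options: FitOptions | None = None) -> FitResult:
    """Fit one Δχ tensor to assigned, measured PCS records.

    Records must carry ``methyl_id``; blanked records are ignored (they
    constrain assignment, not the tensor).  Raises on fewer than 8 fittable
    records (the fit has 8 free parameters).
    """
    opt = options or FitOptions()
    points, obs, w, kept = _evaluation_points(records, methyls)
    if len(kept) < MIN_RECORDS:
        raise ValueError(
            f"under-determined system: {len(kept)} records < {MIN_RECORDS} parameters"
        )
    if opt.initial_metal is not None:
        m0 = np.asarray(opt.initial_metal, float)
    else:
        m0 = points.mean(axis=0)

    rng = np.random.default_rng(opt.seed)
    if opt.fix_metal:
        starts = [m0]
    else:
        starts = [m0]
        for _ in range(opt.n_starts):
            v = rng.normal(size=3)
            v *= (opt.jitter * rng.random() ** (1 / 3)) / np.linalg.norm(v)
            starts.append(m0 + v)

    min_r2 = opt.min_r**2
    prior = None
    if opt.prior_center is not None:
        prior = np.asarray(opt.prior_center, float)

    def resid(metal):
        d = points - metal
        if np.any(np.einsum("ij,ij->i", d, d) < min_r2):
            out = np.full(len(obs), 1e6)
        else:
            out = _solve_at_metal(metal, points, obs, w)[1]
        if prior is not None:
            excess = max(0.0, float(np.linalg.norm(metal - prior)) - opt.prior_radius)
            out = np.append(out, opt.prior_weight * excess)
        return out

    best = None
    for s in starts:
        if opt.fix_metal:
            metal, cost = s, float(np.sum(resid(s) ** 2))
        else:
            sol = least_squares(resid, s, method="lm", ftol=opt.ftol, xtol=opt.xtol)
            metal, cost = sol.x, float(2 * sol.cost)
        if best is None or cost < best[1]:
            best = (metal, cost)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError("no convergent start in tensor fit")

    metal, _ = best
    chi5, wres = _solve_at_metal(metal, points, obs, w)
    cost = float(np.sum(wres**2))  # data term only, prior excluded
    tensor = chi_to_tensor(_chi_from_components(chi5), metal)
    calc = pcs_forward(tensor, points, min_r=opt.min_r)
    residuals = obs - calc
    try:
        m_slope, y0 = regression_stats(obs, calc)
    except ValueError:
        m_slope, y0 = float("nan"), float("nan")
    return FitResult(
        tensor=tensor,
        records=kept,
        residuals=residuals,
        q=q_factor(obs, calc),
        slope=m_slope,
        intercept=y0,
        objective=cost,
        n_starts_tried=len(starts),
    )


def monte_carlo_errors(
    records,
    methyls,
    n_samples: int = 100,
    omit_fraction: float = 0.2,
    seed: int = 0,
    options: FitOptions | None = None,
    base: FitResult | None = None,
) -> dict:
    """Monte-Carlo parameter uncertainties by random data omission.

    Refits the tensor ``n_samples`` times on random subsets with
    ``omit_fraction`` of the records left out, and returns standard deviations
    of the UTR parameters over the refits.  Refits start from the full-data
    optimum (single start).  Deterministic under ``seed``.  Subsets that are
    under-determined are skipped and counted.
    """
    opt = options or FitOptions()
    if base is None:
        base = fit_tensor(records, methyls, opt)
    fittable = [r for r in records if r.value is not None and r.methyl_id is not None]
    rng = np.random.default_rng(seed)
    n_keep = max(int(round(len(fittable) * (1 - omit_fraction))), 0)
    refit_opt = FitOptions(
        initial_metal=base.tensor.metal,
        n_starts=0,
        fix_metal=opt.fix_metal,
        min_r=opt.min_r,
    )
    samples = {"dchi_ax": [], "dchi_rh": [], "x": [], "y": [], "z": []}
    skipped = 0
    for _ in range(n_samples):
        idx = rng.choice(len(fittable), size=n_keep, replace=False)
        subset = [fittable[i] for i in sorted(idx)]
        try:
            res = fit_tensor(subset, methyls, refit_opt)
        except (ValueError, RuntimeError):
            skipped += 1
            continue
        t = res.tensor
        samples["dchi_ax"].append(t.dchi_ax)
        samples["dchi_rh"].append(t.dchi_rh)
        for k, v in zip("xyz", t.metal):
            samples[k].append(v)
    out = {k: float(np.std(v)) if v else float("nan") for k, v in samples.items()}
    out["n_samples"] = n_samples - skipped
    out["n_skipped"] = skipped
    return out


def leave_out_refit(records, methyls, methyl_id: str, options: FitOptions | None = None):
    """Sensitivity check: refit without one methyl's PCSs.

    Returns (delta, refit) where ``delta`` holds the parameter changes of the
    refit relative to the full fit and the refit tensor's prediction errors
    for the held-out records.  Methyls carrying large PCSs perturb the tensor
    more when removed than methyls with small PCSs.
    """
    opt = options or FitOptions()
    base = fit_tensor(records, methyls, opt)
    keep = [r for r in records if r.methyl_id != methyl_id]
    held = [r for r in records if r.methyl_id == methyl_id and r.value is not None]
    if not held:
        raise ValueError(f"methyl {methyl_id} has no measured records")
    refit = fit_tensor(keep, methyls, FitOptions(
        initial_metal=base.tensor.metal, n_starts=4, jitter=opt.jitter,
        fix_metal=opt.fix_metal, seed=opt.seed, min_r=opt.min_r,
    ))
    by_id = {m.methyl_id: m for m in methyls}
    m = by_id[methyl_id]
    pred_err = []
    for r in held:
        point = m.proton_position if r.nucleus == "H" else m.carbon_position
        pred_err.append(r.value - pcs_forward(refit.tensor, point, min_r=opt.min_r))
    delta = {
        "d_dchi_ax": refit.tensor.dchi_ax - base.tensor.dchi_ax,
        "d_dchi_rh": refit.tensor.dchi_rh - base.tensor.dchi_rh,
        "d_metal": float(np.linalg.norm(refit.tensor.metal - base.tensor.metal)),
        "held_out_errors": np.array(pred_err),
    }
    return delta, refit
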