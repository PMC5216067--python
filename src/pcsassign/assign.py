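"""Iterative PCS-based methyl assignment.

The assignment strategy: cross-peaks that can be identified from first
principles (residue-type uniqueness within a labeled subunit, or far methyls
whose PCS magnitudes order by distance from the tag) seed an initial set of
peak→methyl assignments.  Those seeds determine approximate Δχ tensors, the
tensors predict PCSs for every methyl, and a minimum-cost bipartite matching
between measured and predicted PCSs yields additional assignments.  Refit,
re-predict, re-match — repeated until the assignment set is stable.

Peaks of methyls close to a strongly paramagnetic lanthanide are broadened
beyond detection; a missing (blanked) peak is consistent with any methyl
inside that lanthanide's blanking radius (default 20 Å for Dy³⁺, 9 Å for the
much weaker Yb³⁺) and penalizes methyls well outside it.  Sharp peaks that
show no PCS in any dataset and match a free-subunit reference spectrum are
nuisance peaks from unassembled subunit and are excluded up front.

Assignments are classified *unambiguous* when the cost gap to the second-best
candidate methyl exceeds a margin threshold and the peak is supported by
measured PCSs in at least two independent datasets; otherwise *tentative*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .fit import FitOptions, fit_tensor
from .peaks import Dataset, PCSRecord, pair_peaks
from .tensor import pcs_forward

logger = logging.getLogger(__name__)

__all__ = [
    "AssignConfig",
    "AssignmentState",
    "Measurements",
    "build_measurements",
    "exclude_nuisance_peaks",
    "seed_assignments",
    "build_cost_matrix",
    "solve_assignment",
    "classify",
    "iterate",
]

INF = np.inf

#: default (¹H, ¹³C) chemical-shift windows per residue type, ppm; used to
#: decide which residue-type classes a cross-peak is compatible with.
SHIFT_WINDOWS = {
    "ILE": ((0.5, 1.0), (9.0, 15.0)),
    "LEU": ((0.6, 1.0), (22.0, 27.0)),
    "VAL": ((0.7, 1.1), (19.0, 24.0)),
    "MET": ((1.6, 2.2), (15.0, 19.0)),
}


@dataclass
class AssignConfig:
    margin_threshold: float = 9.0  # ≈3σ² gap in combined normalized cost
    unambiguous_cost: float = 4.0  # max per-term cost (≈2σ residuals) for the
    # unambiguous grade: a winning but poorly-fitting mapping stays tentative
    blanking_radius: dict = field(default_factory=lambda: {"Dy": 20.0, "Yb": 9.0})
    blanking_slack: float = 5.0  # Å beyond the radius before a blank penalizes
    blank_penalty: float = 9.0
    outlier_ceiling: float = 25.0  # per-term normalized cost (≈5σ²) above which
    # a candidate pair is rejected
    q_ceiling: float = 0.3  # do not commit mappings that push a group's Q above this
    repair_window: tuple = (0.03, 0.15)  # ppm window around predicted tagged positions
    repair_margin: float = 9.0  # rival-cost gap below which a re-pairing is withheld
    max_iter: int = 20
    shift_windows: dict = field(default_factory=lambda: dict(SHIFT_WINDOWS))
    window_pad: tuple = (0.05, 0.5)  # ppm pad (1H, 13C) on the class windows
    min_seed_magnitude: float = 3.0  # |PCS|/tol needed for magnitude-rank seeds
    # tensor bootstrap: coarse grid of candidate metal positions inside the
    # covalent reach of the tagged side chain, χ solved linearly from the
    # seed records at each candidate and scored by minimum-cost matching
    bootstrap_radius: float = 12.0  # Å, grid ball radius around the tag Cβ
    bootstrap_spacing: float = 3.0  # Å, grid spacing
    bootstrap_polish: int = 20  # candidates refined by match-refit alternation
    bootstrap_accept: float = 3.0  # max mean per-term cost to accept a tensor
    seed: int = 0
    fit_options: dict = field(default_factory=dict)


@dataclass
class Assignment:
    methyl_id: str
    status: str  # unambiguous / tentative
    margin: float
    cost: float = 0.0
    n_support: int = 0
    # peak compatible with >1 residue-type class (e.g. the Leu/Val ¹³C
    # overlap region): such assignments need a stronger margin to be graded
    # unambiguous
    class_ambiguous: bool = False
    # methyl inside some lanthanide's blanking reach: part of its evidence
    # is "absence excused", so the unambiguous grade also needs a stronger
    # margin (near-tag assignments were the hard cases in practice)
    near_blanking: bool = False


@dataclass
class AssignmentState:
    """Peak→methyl mapping per labeled subunit with classification."""

    assignments: dict = field(default_factory=dict)  # (subunit, peak_id) -> Assignment
    iteration: int = 0
    converged: bool = False
    oscillated: bool = False
    residuals: dict = field(default_factory=dict)  # dataset_id -> ppm residual list

    def mapping(self, subunit=None):
        return {
            key: a.methyl_id
            for key, a in self.assignments.items()
            if subunit is None or key[0] == subunit
        }

    def counts(self):
        out = {"unambiguous": 0, "tentative": 0}
        for a in self.assignments.values():
            out[a.status] = out.get(a.status, 0) + 1
        return out

    def signature(self):
        return tuple(sorted((k, a.methyl_id, a.status) for k, a in self.assignments.items()))


# ---------------------------------------------------------------------------
# measurement pooling across datasets of one labeled subunit


@dataclass
class MasterPeak:
    peak_id: str
    h_ppm: float
    c_ppm: float
    intensity: float = 1.0


@dataclass
class Measurements:
    """Per-subunit master peak list plus per-dataset measured/blanked PCSs.

    ``values[dataset_id][master_peak_id][nucleus]`` is a measured PCS in ppm;
    ``blanked[dataset_id]`` is the set of master peaks broadened beyond
    detection in that dataset.  Master peaks unify the untagged cross-peaks of
    one labeled subunit across its datasets.  Peaks in ``present`` but in
    neither ``values`` nor ``blanked`` had ambiguous pairings (crossing
    diagonal trajectories) and await prediction-guided re-pairing.
    """

    master: dict  # subunit -> list of MasterPeak
    values: dict  # dataset_id -> {peak_id: {nucleus: value}}
    blanked: dict  # dataset_id -> set of peak ids
    present: dict  # dataset_id -> set of peak ids present in the untagged list
    datasets: list
    untagged_by_master: dict = field(default_factory=dict)  # ds_id -> {pid: Peak}
    excluded_master: dict = field(default_factory=dict)  # subunit -> [MasterPeak]


def build_measurements(
    datasets, master_window=(0.05, 0.3), ambiguity_margin: float | None = 9.0
) -> Measurements:
    """Pair tagged/untagged lists of every dataset and unify each subunit's
    untagged peaks into one master list.

    Initial pairing is conservative: pairs whose diagonal-displacement cost
    is nearly matched by a rival pairing are withheld (no measured value, no
    blanked flag) until tensor predictions can arbitrate.
    """
    by_subunit = {}
    for ds in datasets:
        by_subunit.setdefault(ds.labeled_subunit, []).append(ds)

    master, values, blanked, present = {}, {}, {}, {}
    untagged_by_master = {}
    for subunit, ds_list in by_subunit.items():
        ds_list = sorted(ds_list, key=lambda d: -len(d.untagged_peaks))
        masters = []
        local_to_master = {}  # (dataset_id, local peak id) -> master id
        for ds in ds_list:
            if not masters:
                for p in sorted(ds.untagged_peaks, key=lambda p: p.peak_id):
                    mid = f"{subunit}:{len(masters) + 1:03d}"
                    masters.append(MasterPeak(mid, p.h_ppm, p.c_ppm, p.intensity))
                    local_to_master[(ds.dataset_id, p.peak_id)] = mid
                continue
            pseudo = [
                type(ds.untagged_peaks[0])(m.peak_id, m.h_ppm, m.c_ppm, m.intensity)
                for m in masters
            ]
            pairing = pair_peaks(ds.untagged_peaks, pseudo, max_shift=master_window)
            for mp, up in pairing.pairs:
                local_to_master[(ds.dataset_id, up.peak_id)] = mp.peak_id
            for up in pairing.unmatched_tagged:
                mid = f"{subunit}:{len(masters) + 1:03d}"
                masters.append(MasterPeak(mid, up.h_ppm, up.c_ppm, up.intensity))
                local_to_master[(ds.dataset_id, up.peak_id)] = mid
        master[subunit] = masters

        for ds in ds_list:
            pairing = pair_peaks(
                ds.tagged_peaks, ds.untagged_peaks, ambiguity_margin=ambiguity_margin
            )
            vals, blank, pres, by_master = {}, set(), set(), {}
            for u in ds.untagged_peaks:
                mid = local_to_master[(ds.dataset_id, u.peak_id)]
                pres.add(mid)
                by_master[mid] = u
            for u, t in pairing.pairs:
                mid = local_to_master[(ds.dataset_id, u.peak_id)]
                v = {}
                for nuc in ds.nuclei:
                    v[nuc] = (t.h_ppm - u.h_ppm) if nuc == "H" else (t.c_ppm - u.c_ppm)
                vals[mid] = v
            for u in pairing.unmatched_untagged:
                blank.add(local_to_master[(ds.dataset_id, u.peak_id)])
            values[ds.dataset_id] = vals
            blanked[ds.dataset_id] = blank
            present[ds.dataset_id] = pres
            untagged_by_master[ds.dataset_id] = by_master
    return Measurements(
        master, values, blanked, present, list(datasets), untagged_by_master
    )


def exclude_nuisance_peaks(meas: Measurements, free_reference=None, tol=(0.008, 0.05)):
    """Remove peaks that show no PCS in any dataset *and* match a free-subunit
    reference list.  Returns the set of removed master peak ids."""
    if not free_reference:
        return set()
    removed = set()
    for subunit, masters in meas.master.items():
        ref = free_reference.get(subunit, [])
        if not ref:
            continue
        for mp in masters:
            near_ref = any(
                abs(mp.h_ppm - r.h_ppm) <= 2 * tol[0] and abs(mp.c_ppm - r.c_ppm) <= 2 * tol[1]
                for r in ref
            )
            if not near_ref:
                continue
            no_pcs = True
            seen = False
            for ds in meas.datasets:
                if ds.labeled_subunit != subunit:
                    continue
                v = meas.values[ds.dataset_id].get(mp.peak_id)
                if v is None:
                    continue
                seen = True
                for nuc, val in v.items():
                    t = tol[0] if nuc == "H" else tol[1]
                    if abs(val) >= 3 * t:
                        no_pcs = False
            if seen and no_pcs:
                removed.add(mp.peak_id)
    for subunit in meas.master:
        meas.excluded_master[subunit] = [
            m for m in meas.master[subunit] if m.peak_id in removed
        ]
        meas.master[subunit] = [m for m in meas.master[subunit] if m.peak_id not in removed]
    for d in meas.values.values():
        for pid in removed:
            d.pop(pid, None)
    for s in meas.blanked.values():
        s -= removed
    for s in meas.present.values():
        s -= removed
    return removed


# ---------------------------------------------------------------------------
# class compatibility and seeding


def compatible_types(peak, windows, pad=(0.05, 0.5)):
    """Residue types whose shift windows (padded) contain the peak."""
    out = set()
    for rtype, ((h0, h1), (c0, c1)) in windows.items():
        if h0 - pad[0] <= peak.h_ppm <= h1 + pad[0] and c0 - pad[1] <= peak.c_ppm <= c1 + pad[1]:
            out.add(rtype)
    return out


def _stereo_allowed(peak_id, methyl, meas, datasets):
    """Stereospecific datasets restrict Leu/Val candidates both ways.

    A sample labeled only at (say) the pro-S methyls shows a cross-peak for a
    Leu/Val methyl iff it is pro-S: presence of the peak in that dataset's
    *untagged* list pins the prochirality, and absence pins the opposite one
    (the untagged list is unaffected by paramagnetic blanking).
    """
    if methyl.stereo == "none":
        return True
    for ds in datasets:
        if ds.stereospecific and ds.labeled_subunit == methyl.subunit:
            present = peak_id in meas.present.get(ds.dataset_id, set())
            if present and methyl.stereo != ds.stereospecific:
                return False
            if not present and methyl.stereo == ds.stereospecific:
                return False
    return True


def seed_assignments(meas: Measurements, methyls, config: AssignConfig | None = None,
                     tag_positions=None) -> AssignmentState:
    """Initial assignments from residue-type uniqueness and the
    magnitude-vs-distance heuristic.

    (a) If a subunit contains exactly one methyl of a residue type and exactly
    one cross-peak compatible with only that type, the two are matched.

    (b) For a residue-type class whose peaks all carry same-sign ¹H PCSs well
    above the noise in some dataset, and whose methyls are all far from the
    tag, |PCS| decreases with distance from the metal; when peak and methyl
    counts agree, ranking peaks by |PCS| against methyls by distance yields
    tentative seeds.  Requires ``tag_positions`` (group -> approximate metal
    position, e.g. the tagged residue's Cβ).
    """
    config = config or AssignConfig()
    state = AssignmentState()
    by_subunit = {}
    for m in methyls:
        by_subunit.setdefault(m.subunit, []).append(m)

    for subunit, masters in meas.master.items():
        sub_methyls = by_subunit.get(subunit, [])
        types_present = {m.restype for m in sub_methyls}
        compat = {
            mp.peak_id: compatible_types(mp, config.shift_windows, config.window_pad)
            & types_present
            for mp in masters
        }
        # peaks blanked (or withheld) everywhere carry no measurable PCS and
        # cannot seed anything
        measured = {
            pid
            for ds in meas.datasets
            if ds.labeled_subunit == subunit
            for pid in meas.values[ds.dataset_id]
        }
        # (a) singleton classes
        for rtype in types_present:
            ms = [m for m in sub_methyls if m.restype == rtype]
            ps = [pid for pid, c in compat.items() if c == {rtype} and pid in measured]
            if len(ms) == 1 and len(ps) == 1:
                state.assignments[(subunit, ps[0])] = Assignment(
                    ms[0].methyl_id, "tentative", margin=INF
                )
        # (b) magnitude-vs-distance ranking
        if tag_positions:
            _magnitude_rank_seeds(
                state, subunit, masters, sub_methyls, compat, meas, config, tag_positions
            )
    return state


def _magnitude_rank_seeds(state, subunit, masters, sub_methyls, compat, meas, config,
                          tag_positions):
    """Distance-vs-magnitude seeding for datasets whose tag sits near one end
    of an elongated structure.

    The PCS angular factor is even in the metal→nucleus direction, so all
    methyls lying in one narrow directional cone from the metal share its
    value (and its sign): their PCSs are then ordered purely by 1/r³.  When
    the methyls surviving paramagnetic blanking all fall in such a cone, the
    visible peaks ranked by |¹H PCS| correspond to the visible methyls ranked
    by distance from the tag.  The heuristic checks its own premises — a
    single cone, uniform peak sign, residue-class consistency of the ranked
    match — and produces nothing when they fail (e.g. mid-structure tags,
    which see far methyls in two cones with different angular factors).
    """
    assigned_peaks = {p for (s, p) in state.assignments if s == subunit}
    assigned_methyls = {a.methyl_id for a in state.assignments.values()}
    tol_h = 0.008
    for ds in meas.datasets:
        if ds.labeled_subunit != subunit:
            continue
        tagpos = tag_positions.get(ds.group)
        if tagpos is None:
            continue
        vals = meas.values[ds.dataset_id]
        ps = [
            mp for mp in masters
            if mp.peak_id in vals and "H" in vals[mp.peak_id]
            and mp.peak_id not in assigned_peaks
        ]
        ms = [m for m in sub_methyls if m.methyl_id not in assigned_methyls]
        if len(ps) < 4 or len(ps) > len(ms):
            continue
        # the len(ps) farthest methyls approximate the visible set (blanking
        # is distance-based); shrink to the largest far prefix lying in one
        # directional cone from the tag
        ms_sorted = sorted(
            ms, key=lambda m: -np.linalg.norm(m.carbon_position - tagpos)
        )
        visible = ms_sorted[: len(ps)]
        dirs = np.array(
            [
                (m.carbon_position - tagpos)
                / np.linalg.norm(m.carbon_position - tagpos)
                for m in visible
            ]
        )
        # only the strictly far subset orders reliably by 1/r³: mid-range
        # methyls mix angular variation into the magnitudes
        n_far = sum(
            1 for m in visible
            if np.linalg.norm(m.carbon_position - tagpos) >= 30.0
        )
        k = min(len(visible), n_far)
        while k >= 4:
            sub = dirs[:k]
            mean_dir = sub.mean(axis=0)
            nrm = np.linalg.norm(mean_dir)
            if nrm > 0 and np.min(sub @ (mean_dir / nrm)) >= 0.8:
                break
            k -= 1
        if k < 4:
            continue  # no usable cone: ordering by distance is unsound
        far_methyls = visible[:k]  # farthest first
        # the k smallest-|PCS| peaks should be those far methyls
        ps_sorted = sorted(ps, key=lambda p: abs(vals[p.peak_id]["H"]))
        far_peaks = ps_sorted[:k]  # smallest shift first
        pcs = np.array([vals[p.peak_id]["H"] for p in far_peaks])
        strong = np.abs(pcs) >= 2 * tol_h
        if strong.sum() < 4:
            continue
        signs = np.sign(pcs[strong])
        if not (np.all(signs > 0) or np.all(signs < 0)):
            continue  # mixed signs contradict the single-cone premise
        pairs = []
        mismatch = 0
        for p, m in zip(far_peaks, far_methyls):
            if abs(vals[p.peak_id]["H"]) < config.min_seed_magnitude * tol_h:
                continue  # too weak to rank against its neighbours
            if m.restype in compat[p.peak_id]:
                pairs.append((p.peak_id, m.methyl_id))
            else:
                mismatch += 1
        if mismatch > 0.25 * k:
            continue  # ranking inconsistent with residue-type classes
        for pid, mid in pairs:
            key = (subunit, pid)
            if key not in state.assignments:
                state.assignments[key] = Assignment(mid, "tentative", margin=0.0)


# ---------------------------------------------------------------------------
# cost matrices and matching


def records_for_group(state: AssignmentState, meas: Measurements, group):
    """Measured PCS records with methyl ids for one (site, lanthanide) group,
    pooled over its datasets, from the current assignments."""
    from .peaks import default_tolerance

    records = []
    for ds in meas.datasets:
        if ds.group != group:
            continue
        vals = meas.values[ds.dataset_id]
        for (subunit, pid), a in state.assignments.items():
            if subunit != ds.labeled_subunit or pid not in vals:
                continue
            for nuc, v in vals[pid].items():
                records.append(
                    PCSRecord(
                        dataset_id=ds.dataset_id,
                        peak_id=pid,
                        nucleus=nuc,
                        value=v,
                        tolerance=default_tolerance(nuc),
                        status="measured",
                        methyl_id=a.methyl_id,
                    )
                )
    return records


def _group_lap(tensor, group, meas: Measurements, methyls, config: AssignConfig,
               forced=None):
    """Minimum-cost matching of measured peaks to methyls for one
    (site, lanthanide) group under a trial tensor.

    Returns (mean per-term normalized squared residual, matched records).
    ``forced`` pins peaks (e.g. uniqueness seeds) to their methyls.
    """
    from .peaks import default_tolerance

    forced = forced or {}
    total, nterm, records = 0.0, 0, []
    for ds in meas.datasets:
        if ds.group != group:
            continue
        sub = ds.labeled_subunit
        vals = meas.values[ds.dataset_id]
        mps = [mp for mp in meas.master.get(sub, []) if mp.peak_id in vals]
        mets = [m for m in methyls if m.subunit == sub]
        if not mps or not mets:
            continue
        pred = {}
        for nuc in ds.nuclei:
            pts = np.array(
                [m.proton_position if nuc == "H" else m.carbon_position for m in mets]
            )
            pred[nuc] = pcs_forward(tensor, pts, min_r=1e-3)
        cost = np.zeros((len(mps), len(mets)))
        for nuc in ds.nuclei:
            v = np.array([vals[mp.peak_id].get(nuc, np.nan) for mp in mps])
            with np.errstate(invalid="ignore"):
                term = ((v[:, None] - pred[nuc][None, :]) / default_tolerance(nuc)) ** 2
            cost += np.nan_to_num(term)
        for i, mp in enumerate(mps):
            fm = forced.get((sub, mp.peak_id))
            if fm is not None:
                allowed = np.array([m.methyl_id == fm for m in mets])
            else:
                ctypes = compatible_types(mp, config.shift_windows, config.window_pad)
                allowed = np.array(
                    [
                        m.restype in ctypes
                        and _stereo_allowed(mp.peak_id, m, meas, meas.datasets)
                        for m in mets
                    ]
                )
            cost[i, ~allowed] = INF
        pairs, _ = solve_assignment(cost)
        for i, j in pairs:
            for nuc, v in vals[mps[i].peak_id].items():
                records.append(
                    PCSRecord(
                        dataset_id=ds.dataset_id,
                        peak_id=mps[i].peak_id,
                        nucleus=nuc,
                        value=v,
                        tolerance=default_tolerance(nuc),
                        status="measured",
                        methyl_id=mets[j].methyl_id,
                    )
                )
                # robust: single corrupt values must not sink a true basin
                total += min(
                    ((v - pred[nuc][j]) / default_tolerance(nuc)) ** 2,
                    config.outlier_ceiling,
                )
                nterm += 1
    return (total / nterm if nterm else INF), records


def bootstrap_group_tensor(group, meas: Measurements, methyls,
                           seeds: AssignmentState, tag_position,
                           config: AssignConfig):
    """Determine one group's Δχ tensor from the seed assignments alone.

    The seed records under-determine the 8-parameter tensor (they solve χ
    exactly at *any* metal position), so the metal is searched on a coarse
    grid inside the tag's covalent reach; at each candidate the χ components
    are solved linearly from the seeds and the resulting tensor is scored by
    the cost of the best peak↔methyl matching over all of the group's data.
    The top candidates are polished by match→refit alternation and the best
    is returned as (tensor, score), or ``None`` when the seeds are too few
    or no candidate scores below ``config.bootstrap_accept``.
    """
    from .fit import FitOptions, fit_tensor, tensor_at_metal

    # only certain assignments (residue-type uniqueness seeds, or mappings
    # already classified unambiguous) enter the linear solve and the forced
    # set; heuristic seeds are not trusted here
    certain = AssignmentState(
        assignments={
            key: a
            for key, a in seeds.assignments.items()
            if not np.isfinite(a.margin) or a.status == "unambiguous"
        }
    )
    seed_records = records_for_group(certain, meas, group)
    if len(seed_records) < 6:
        return None
    forced = {key: a.methyl_id for key, a in certain.assignments.items()}
    steps = np.arange(-config.bootstrap_radius, config.bootstrap_radius + 1e-9,
                      config.bootstrap_spacing)
    candidates = []
    for dx in steps:
        for dy in steps:
            for dz in steps:
                v = np.array([dx, dy, dz])
                r = np.linalg.norm(v)
                if not (2.0 <= r <= config.bootstrap_radius):
                    continue
                t = tensor_at_metal(seed_records, methyls, tag_position + v, min_r=1.0)
                if t is None:
                    continue
                score, _ = _group_lap(t, group, meas, methyls, config, forced)
                candidates.append((score, t))
    candidates.sort(key=lambda x: x[0])
    # polish a *diverse* subset: best-scoring candidates subject to a minimum
    # metal separation, so each distinct basin in the prior ball gets polished
    chosen = []
    for s, t in candidates:
        if len(chosen) >= config.bootstrap_polish:
            break
        if all(np.linalg.norm(t.metal - t2.metal) >= 4.0 for _, t2 in chosen):
            chosen.append((s, t))
    polished = []
    for _, t in chosen:
        for _ in range(3):
            _, recs = _group_lap(t, group, meas, methyls, config, forced)
            if len(recs) < 8:
                break
            try:
                res = fit_tensor(
                    recs, methyls,
                    FitOptions(initial_metal=t.metal, n_starts=0,
                               prior_center=tag_position, min_r=1e-3),
                )
            except (ValueError, RuntimeError):
                break
            t = res.tensor
        score, _ = _group_lap(t, group, meas, methyls, config, forced)
        if score <= config.bootstrap_accept:
            polished.append((t, score))
    # distinct basins only: drop near-duplicates of better-scoring tensors
    polished.sort(key=lambda x: x[1])
    distinct = []
    for t, s in polished:
        dup = any(
            np.linalg.norm(t.metal - t2.metal) < 2.0
            and abs(t.dchi_ax - t2.dchi_ax) < 2.0
            for t2, _ in distinct
        )
        if not dup:
            distinct.append((t, s))
        if len(distinct) == 3:
            break
    return distinct or None


def _rival_gap(cost, i, j):
    """Gap between cost[i, j] and the best alternative in its row or column."""
    alt_row = np.delete(cost[i, :], j)
    alt_col = np.delete(cost[:, j], i)
    rival = min(
        alt_row.min() if alt_row.size else np.inf,
        alt_col.min() if alt_col.size else np.inf,
    )
    return rival - cost[i, j]


def _filtered_tagged(ds, meas: Measurements):
    """Tagged peaks of a dataset with nuisance peaks (matching an excluded
    free-subunit master within noise) removed."""
    excl = meas.excluded_master.get(ds.labeled_subunit, [])
    return [
        tp for tp in ds.tagged_peaks
        if not any(
            abs(tp.h_ppm - e.h_ppm) <= 3 * 0.008 and abs(tp.c_ppm - e.c_ppm) <= 3 * 0.05
            for e in excl
        )
    ]


def extract_fit_records(state: AssignmentState, meas: Measurements, tensors: dict,
                        methyls, config: AssignConfig) -> dict:
    """Measured PCS records for tensor fitting, derived fresh from the raw
    peak lists and the committed assignments.

    For every dataset with a tensor, the tagged position of each committed
    (peak, methyl) pair is predicted as untagged + PCS(methyl) and matched
    against the tagged peaks (one linear-assignment problem per dataset,
    window ``config.repair_window``); an accepted match contributes
    value = δ(tagged) − δ(untagged) per nucleus.  Matches with a rival
    within ``config.repair_margin`` are withheld, so overlapping peaks never
    inject values.  Nothing persists between iterations: records always
    re-derive from the raw spectra and the current state, which keeps the
    loop self-correcting.  Returns {group: [PCSRecord, ...]}.
    """
    from .peaks import default_tolerance

    win_h, win_c = config.repair_window
    by_id = {m.methyl_id: m for m in methyls}
    out = {}
    for ds in meas.datasets:
        t = tensors.get(ds.group)
        if t is None:
            continue
        sub = ds.labeled_subunit
        u_by_master = meas.untagged_by_master[ds.dataset_id]
        tagged = _filtered_tagged(ds, meas)
        entries = []  # (pid, methyl_id, predicted tagged h, predicted tagged c)
        for (s, pid), a in state.assignments.items():
            if s != sub or pid not in u_by_master:
                continue
            m = by_id[a.methyl_id]
            u = u_by_master[pid]
            entries.append(
                (
                    pid,
                    a.methyl_id,
                    u.h_ppm + pcs_forward(t, m.proton_position, min_r=1e-3),
                    u.c_ppm + pcs_forward(t, m.carbon_position, min_r=1e-3),
                )
            )
        if not entries or not tagged:
            continue
        big = 1e12
        cost = np.full((len(entries), len(tagged)), big)
        for i, (_, _, ph, pc) in enumerate(entries):
            for j, tp in enumerate(tagged):
                dh, dc = tp.h_ppm - ph, tp.c_ppm - pc
                if abs(dh) > win_h or abs(dc) > win_c:
                    continue
                cost[i, j] = (dh / 0.008) ** 2 + (dc / 0.05) ** 2
        rows, cols = linear_sum_assignment(cost)
        recs = out.setdefault(ds.group, [])
        for i, j in zip(rows, cols):
            if cost[i, j] >= big:
                continue
            if _rival_gap(cost, i, j) < config.repair_margin:
                continue
            pid, mid, _, _ = entries[i]
            u = u_by_master[pid]
            tp = tagged[j]
            for nuc in ds.nuclei:
                v = (tp.h_ppm - u.h_ppm) if nuc == "H" else (tp.c_ppm - u.c_ppm)
                recs.append(
                    PCSRecord(
                        dataset_id=ds.dataset_id,
                        peak_id=pid,
                        nucleus=nuc,
                        value=v,
                        tolerance=default_tolerance(nuc),
                        status="measured",
                        methyl_id=mid,
                    )
                )
    return out


def build_cost_matrix(
    subunit,
    meas: Measurements,
    methyls,
    tensors: dict,
    config: AssignConfig,
):
    """Cost matrix peaks × methyls for one labeled subunit, scored directly
    against the raw tagged spectra.

    For each dataset with a fitted tensor, hypothesis (peak u, methyl m)
    predicts the tagged position u + PCS(m); its cost term is the
    tolerance-normalized squared distance to the nearest tagged peak, capped
    at ``outlier_ceiling`` per nucleus.  A missing tagged peak costs nothing
    when m lies inside the lanthanide's blanking radius (broadening explains
    the absence) and ``blank_penalty`` per nucleus when m is far outside it.
    Pairs violating the residue-type class or a stereospecific restriction
    get infinite cost.  Because every term compares predictions with raw
    peaks, no derived quantity can feed back on itself.

    Returns (peak ids, methyl ids, cost, n_terms, support) where ``support``
    counts datasets contributing a real (non-blank) spectral match.
    """
    masters = meas.master.get(subunit, [])
    sub_methyls = [m for m in methyls if m.subunit == subunit]
    np_, nm = len(masters), len(sub_methyls)
    cost = np.zeros((np_, nm))
    n_terms = np.zeros((np_, nm), dtype=int)
    support = np.zeros((np_, nm), dtype=int)
    if np_ == 0 or nm == 0:
        return [], [], cost, n_terms, support

    for ds in meas.datasets:
        t = tensors.get(ds.group)
        if t is None or ds.labeled_subunit != subunit:
            continue
        # matching always uses both spectral dimensions (the cross-peak is a
        # 2D position even when only one nucleus' PCS value is recorded)
        ndim = 2
        strong = config.outlier_ceiling * ndim  # a credible spectral match
        tagged = _filtered_tagged(ds, meas)
        th = np.array([tp.h_ppm for tp in tagged])
        tc = np.array([tp.c_ppm for tp in tagged])
        pred_h = pcs_forward(
            t, np.array([m.proton_position for m in sub_methyls]), min_r=1e-3
        )
        pred_c = pcs_forward(
            t, np.array([m.carbon_position for m in sub_methyls]), min_r=1e-3
        )
        dist = np.array(
            [np.linalg.norm(m.carbon_position - t.metal) for m in sub_methyls]
        )
        radius = config.blanking_radius.get(ds.lanthanide, 0.0)
        blankable = dist <= radius + config.blanking_slack
        pres = meas.present[ds.dataset_id]
        u_by_master = meas.untagged_by_master[ds.dataset_id]
        for i, mp in enumerate(masters):
            if mp.peak_id not in pres or mp.peak_id not in u_by_master:
                continue
            u = u_by_master[mp.peak_id]
            ph = u.h_ppm + pred_h  # per-methyl predicted tagged position
            pc = u.c_ppm + pred_c
            if len(tagged):
                d2 = ((th[None, :] - ph[:, None]) / 0.008) ** 2 + (
                    (tc[None, :] - pc[:, None]) / 0.05
                ) ** 2
                near = d2.min(axis=1)
            else:
                near = np.full(nm, np.inf)
            matched = near <= strong
            # matched terms are centred on their noise expectation (χ² ≈ 1
            # per dimension) so hypotheses with different numbers of
            # contributing datasets compare without bias
            term = np.where(matched, near - ndim, np.where(
                blankable, 0.0, config.blank_penalty * ndim
            ))
            cost[i] += term
            n_terms[i] += np.where(matched | ~blankable, ndim, 0)
            support[i] += matched.astype(int)

    for i, mp in enumerate(masters):
        ctypes = compatible_types(mp, config.shift_windows, config.window_pad)
        for j, m in enumerate(sub_methyls):
            if m.restype not in ctypes or not _stereo_allowed(
                mp.peak_id, m, meas, meas.datasets
            ):
                cost[i, j] = INF
    return (
        [m.peak_id for m in masters],
        [m.methyl_id for m in sub_methyls],
        cost,
        n_terms,
        support,
    )


def solve_assignment(cost):
    """Minimum-cost injective matching on a rectangular cost matrix.

    Infinite entries mark disallowed pairs; peaks whose row is all-infinite
    are left unassigned.  Returns (list of (row, col), margins) where
    margin[row] is the cost gap to the row's second-best allowed column
    (0 for exact ties, inf when no alternative exists).
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return [], {}
    big = 1e15
    capped = np.where(np.isfinite(cost), cost, big)
    rows, cols = linear_sum_assignment(capped)
    pairs, margins = [], {}
    for i, j in zip(rows, cols):
        if not np.isfinite(cost[i, j]):
            continue
        pairs.append((i, j))
        alt = np.delete(cost[i], j)
        alt = alt[np.isfinite(alt)]
        margins[i] = float(alt.min() - cost[i, j]) if alt.size else INF
    return pairs, margins


def classify(state: AssignmentState, margin_threshold: float,
             unambiguous_cost: float = 4.0, n_terms=None) -> AssignmentState:
    """Promote assignments to *unambiguous* when (a) the cost gap to the
    second-best methyl clears the margin threshold, (b) at least two
    independent datasets contribute spectral matches, and (c) the winning
    cost itself is plausible (≤ ``unambiguous_cost`` per term — a mapping
    that wins by default while fitting poorly stays tentative)."""
    n_terms = n_terms or {}
    for key, a in state.assignments.items():
        terms = max(n_terms.get(key, a.n_support), 1)
        # hard-case categories demand disproportionately stronger margins:
        # near-blanking evidence is partly "absence excused", and class-
        # ambiguous peaks can be confidently wrong across Leu/Val
        need = margin_threshold
        if a.class_ambiguous:
            need = max(need, 3.0 * margin_threshold)
        if a.near_blanking:
            need = max(need, 5.0 * margin_threshold)
        if (
            a.margin >= need
            and a.n_support >= 2
            and a.cost <= unambiguous_cost * terms
        ):
            a.status = "unambiguous"
        else:
            a.status = "tentative"
    return state


# ---------------------------------------------------------------------------
# the iterative loop


def iterate(
    datasets,
    methyls,
    config: AssignConfig | None = None,
    tag_positions=None,
    free_reference=None,
    initial_state: AssignmentState | None = None,
    measurements: Measurements | None = None,
):
    """Run the seed → fit → predict → match loop to convergence.

    Parameters
    ----------
    datasets:
        :class:`~pcsassign.peaks.Dataset` objects with peak lists attached.
    methyls:
        All candidate methyls (across subunits), with ``subunit`` labels.
    tag_positions:
        Mapping (tag site, lanthanide) group -> approximate metal position
        (the tagged residue's Cβ); used to initialize tensor fits and for
        magnitude-rank seeding.
    free_reference:
        Optional subunit -> peak list of the free (unassembled) subunit, used
        to exclude nuisance peaks.

    Returns (state, fits) where ``fits`` maps each group to its final
    :class:`~pcsassign.fit.FitResult`.
    """
    config = config or AssignConfig()
    meas = measurements or build_measurements(datasets)
    exclude_nuisance_peaks(meas, free_reference)

    groups = sorted({ds.group for ds in datasets})
    subunits = sorted(meas.master)

    state = initial_state or seed_assignments(meas, methyls, config, tag_positions)
    # At least one group must be determinable from the seeds alone; the other
    # groups (typically the weakly-shifting lanthanide) bootstrap later, once
    # assignments made with the first tensors supply them enough records.
    seed_counts = {g: len(records_for_group(state, meas, g)) for g in groups}
    if not any(n >= 8 for n in seed_counts.values()):
        raise ValueError(
            f"seeding produced too few records in every group ({seed_counts}); "
            "at least 8 are needed to determine a tensor"
        )

    tensors: dict = {}
    fits: dict = {}

    def fit_group(g, records):
        """Refit group ``g``'s tensor from measured, assigned records.

        Records from not-yet-correct assignments contaminate the pool, so
        the fit is robustified by trimming: records whose tolerance-scaled
        residual exceeds 5σ under the current fit are dropped and the tensor
        refit (two passes at most)."""
        if len(records) < 8:
            return False
        init = tensors[g].metal if g in tensors else (
            tag_positions.get(g) if tag_positions else None
        )
        # two lanthanides on the same tag site share (nearly) the same metal
        # position; the better-determined sibling's fitted center softly
        # anchors the weaker fit (typically the ¹H-only Yb group)
        prior_c = tag_positions.get(g) if tag_positions else None
        prior_r, prior_w = 12.0, 10.0
        sib = None
        for g2, f2 in fits.items():
            if g2 != g and g2[0] == g[0] and len(f2.records) > len(records):
                if sib is None or len(f2.records) > len(fits[sib].records):
                    sib = g2
        if sib is not None:
            prior_c, prior_r, prior_w = fits[sib].tensor.metal, 2.0, 20.0
        opt = FitOptions(
            initial_metal=init, n_starts=4 if g in tensors else 16,
            seed=config.seed, min_r=1e-3,
            prior_center=prior_c, prior_radius=prior_r, prior_weight=prior_w,
            **config.fit_options,
        )
        try:
            res = fit_tensor(records, methyls, opt)
            for _ in range(3):
                keep = [
                    r for r, dr in zip(res.records, res.residuals)
                    if abs(dr) <= 3 * r.tolerance
                ]
                if len(keep) < 8 or len(keep) == len(res.records):
                    break
                trim_opt = replace(opt, initial_metal=res.tensor.metal, n_starts=2)
                res = fit_tensor(keep, methyls, trim_opt)
        except (ValueError, RuntimeError) as exc:
            logger.warning("fit failed for group %s: %s", g, exc)
            return False
        tensors[g] = res.tensor
        fits[g] = res
        return True

    def joint_cost(trial_tensors):
        """Total normalized matching cost over all subunits for a candidate
        set of group tensors — the cross-group consistency criterion."""
        tot, terms = 0.0, 0
        for subunit in subunits:
            pids, mids, cost, n_terms, _ = build_cost_matrix(
                subunit, meas, methyls, trial_tensors, config
            )
            pairs, _ = solve_assignment(cost)
            for i, j in pairs:
                if n_terms[i, j] >= 1:
                    tot += cost[i, j]
                    terms += n_terms[i, j]
        return tot / terms if terms else INF

    # --- initial tensors: metal-grid bootstrap from the seeds (groups whose
    # seeds are too sparse — typically the weak lanthanide — join later, once
    # assignments made with the first tensors supply them enough records).
    # Each group may return several candidate basins; the combination that
    # minimizes the joint matching cost across all groups is kept.
    if tag_positions:
        cand_by_group = {}
        for g in groups:
            if g not in tag_positions:
                continue
            out = bootstrap_group_tensor(
                g, meas, methyls, state, tag_positions[g], config
            )
            if out:
                cand_by_group[g] = out
        if cand_by_group:
            import itertools as _it

            keys = sorted(cand_by_group)
            lists = [cand_by_group[g] for g in keys]
            # cap the enumeration; later lists reduced to their best candidate
            while int(np.prod([len(l) for l in lists])) > 27:
                longest = max(range(len(lists)), key=lambda i: len(lists[i]))
                lists[longest] = lists[longest][:-1]
            best_combo, best_score = None, INF
            for combo in _it.product(*lists):
                trial = {g: t for g, (t, _) in zip(keys, combo)}
                s = joint_cost(trial)
                if s < best_score:
                    best_combo, best_score = trial, s
            tensors.update(best_combo)
            logger.info("bootstrap joint cost %.2f for %s", best_score, keys)
    if not tensors:
        for g in groups:
            fit_group(g, records_for_group(state, meas, g))
    if not tensors:
        raise RuntimeError("no group tensor could be determined from the seeds")

    seen_signatures = {state.signature()}
    iteration = 0
    group_records: dict = {}
    challenged: dict = {}  # group -> certain-assignment count at last challenge
    dropped: set = set()  # groups whose tensor was evicted at a stability check
    for iteration in range(1, config.max_iter + 1):
        # --- match peaks to methyls per subunit against the raw spectra
        new_state = AssignmentState(iteration=iteration)
        terms_by_key = {}
        for subunit in subunits:
            pids, mids, cost, n_terms, support = build_cost_matrix(
                subunit, meas, methyls, tensors, config
            )
            by_mid = {m.methyl_id: m for m in methyls if m.subunit == subunit}

            def _near_blanking(mid):
                m = by_mid[mid]
                for g, t in tensors.items():
                    radius = config.blanking_radius.get(g[1], 0.0)
                    if (
                        np.linalg.norm(m.carbon_position - t.metal)
                        <= radius + config.blanking_slack
                    ):
                        return True
                return False

            types_present = {m.restype for m in methyls if m.subunit == subunit}
            n_classes = {
                mp.peak_id: len(
                    compatible_types(mp, config.shift_windows, config.window_pad)
                    & types_present
                )
                for mp in meas.master[subunit]
            }
            pairs, margins = solve_assignment(cost)
            for i, j in pairs:
                if support[i, j] < 1:
                    continue  # no spectral evidence for this pair at all
                if cost[i, j] > config.outlier_ceiling * max(n_terms[i, j], 1):
                    continue  # inconsistent with every tensor: leave out
                key = (subunit, pids[i])
                new_state.assignments[key] = Assignment(
                    mids[j],
                    "tentative",
                    margin=margins[i],
                    cost=float(cost[i, j]),
                    n_support=int(support[i, j]),
                    class_ambiguous=n_classes.get(pids[i], 1) > 1,
                    near_blanking=_near_blanking(mids[j]),
                )
                terms_by_key[key] = int(n_terms[i, j])
        classify(new_state, config.margin_threshold, config.unambiguous_cost, terms_by_key)

        if not new_state.assignments:
            logger.warning("candidate mapping collapsed; keeping previous state")
            break

        # --- refit every determinable tensor from the committed mapping,
        # with values re-derived from the raw peak lists; a group whose fit
        # stays poor is re-bootstrapped from the current assignments
        group_records = extract_fit_records(new_state, meas, tensors, methyls, config)
        certain_seeds = {
            key: a.methyl_id
            for key, a in state.assignments.items()
            if not np.isfinite(a.margin)
        }
        for g in groups:
            if g in tensors:
                # challenge: a tensor whose free matching of the conservative
                # measurements stays poor sits in a wrong basin; rebuild it
                # from the (now richer) current assignments
                # a challenge is worth repeating only once new information
                # (a larger pool of trusted assignments) has accumulated
                n_certain = sum(
                    1 for a in new_state.assignments.values()
                    if a.status == "unambiguous"
                ) + len(certain_seeds)
                if challenged.get(g, -1) < n_certain - 4:
                    s, _ = _group_lap(
                        tensors[g], g, meas, methyls, config, certain_seeds
                    )
                    if (
                        s > config.bootstrap_accept
                        and tag_positions
                        and g in tag_positions
                    ):
                        challenged[g] = n_certain
                        out = bootstrap_group_tensor(
                            g, meas, methyls, new_state, tag_positions[g], config
                        )
                        if out and out[0][1] < s:
                            tensors[g] = out[0][0]
                            group_records = extract_fit_records(
                                new_state, meas, tensors, methyls, config
                            )
            if g not in tensors:
                # a group that could not be bootstrapped initially joins once
                # the other groups' assignments give it enough usable records
                if not fit_group(g, records_for_group(new_state, meas, g)) and (
                    tag_positions and g in tag_positions
                ):
                    out = bootstrap_group_tensor(
                        g, meas, methyls, new_state, tag_positions[g], config
                    )
                    if out:
                        tensors[g] = out[0][0]
                if g in tensors:
                    group_records = extract_fit_records(
                        new_state, meas, tensors, methyls, config
                    )
            fit_group(g, group_records.get(g, []))
            if (
                g in fits
                and fits[g].q > config.q_ceiling
                and tag_positions
                and g in tag_positions
            ):
                out = bootstrap_group_tensor(
                    g, meas, methyls, new_state, tag_positions[g], config
                )
                if out:
                    tensors[g] = out[0][0]
                    group_records = extract_fit_records(
                        new_state, meas, tensors, methyls, config
                    )
                    fit_group(g, group_records.get(g, []))

        sig = new_state.signature()
        stable = sig == state.signature() or sig in seen_signatures
        if stable:
            # last resort before accepting: a group whose tensor still cannot
            # explain the conservative measurements is evicted outright; the
            # loop continues on the healthy groups and the evicted one
            # rejoins later from their (cleaner) assignments
            evicted = False
            for g in list(tensors):
                if g in dropped:
                    continue
                s, _ = _group_lap(tensors[g], g, meas, methyls, config, certain_seeds)
                if s > config.bootstrap_accept:
                    logger.warning("evicting ill-fitting tensor for group %s", g)
                    dropped.add(g)
                    tensors.pop(g, None)
                    fits.pop(g, None)
                    evicted = True
            if evicted:
                seen_signatures = {sig}
                state = new_state
                continue
        if sig == state.signature():
            state = new_state
            state.converged = True
            break
        if sig in seen_signatures:
            state = new_state
            state.oscillated = True
            logger.warning("assignment oscillation detected; stopping")
            break
        seen_signatures.add(sig)
        state = new_state

    state.iteration = iteration

    # final per-dataset residuals from the raw-spectrum-derived records
    by_id = {m.methyl_id: m for m in methyls}
    group_records = extract_fit_records(state, meas, tensors, methyls, config)
    for g, records in group_records.items():
        t = tensors[g]
        for r in records:
            m = by_id[r.methyl_id]
            point = m.proton_position if r.nucleus == "H" else m.carbon_position
            state.residuals.setdefault(r.dataset_id, []).append(
                r.value - pcs_forward(t, point, min_r=1e-3)
            )
    return state, fits


def format_assignment_table(state: AssignmentState, methyls, meas: Measurements) -> str:
    """Tabular text: subunit, chain, residue, type, methyl, stereo, shifts,
    status, margin — one row per assigned peak."""
    by_id = {m.methyl_id: m for m in methyls}
    peak_by_id = {
        (s, mp.peak_id): mp for s, masters in meas.master.items() for mp in masters
    }
    lines = [
        "subunit\tchain\tresnum\trestype\tmethyl\tstereo\t1H_ppm\t13C_ppm\tstatus\tmargin"
    ]
    for (subunit, pid), a in sorted(state.assignments.items()):
        m = by_id[a.methyl_id]
        p = peak_by_id[(subunit, pid)]
        margin = f"{a.margin:.2f}" if np.isfinite(a.margin) else "inf"
        lines.append(
            f"{subunit}\t{m.chain}\t{m.resnum}\t{m.restype}\t{m.methyl}\t{m.stereo}\t"
            f"{p.h_ppm:.3f}\t{p.c_ppm:.3f}\t{a.status}\t{margin}"
        )
    return "\n".join(lines) + "\n"
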