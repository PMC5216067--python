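"""Synthetic data with ground truth: idealized helix bundles, Δχ tensors and
paired tagged/untagged peak lists.

The generator emulates the experimental design of PCS-based methyl
assignment on a multi-subunit helical bundle: one subunit at a time carries
the ¹³CH₃ labels, a lanthanide chelator sits on an engineered cysteine of
(usually) another subunit, and each (labeled subunit × tag site × lanthanide)
combination yields one pair of 2D peak lists.  Every stochastic element —
base chemical shifts, tensor magnitudes and orientations, shift noise,
nuisance peaks — flows from a single seed, and the ground truth (true
tensors, peak→methyl map, blanked methyls) is recorded for every dataset.

What is emulated: point-metal PCSs, Gaussian shift noise at the measurement
precisions (0.008 ppm ¹H, 0.05 ppm ¹³C), hard-radius paramagnetic blanking
(default 20 Å for Dy³⁺, 9 Å for Yb³⁺), 50%-labeled Leu/Val methyl pairs with
optional stereospecific restriction, poor chemical-shift dispersion via
narrow per-residue-type shift windows, and sharp nuisance peaks from
unassembled subunit that carry no PCS.  Not emulated: lineshapes, relaxation
rates, tag-conformer ensembles (blanking is a hard radius, not a relaxation
model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .peaks import Dataset, Peak, write_peaklist
from .structure import StructureModel, extract_methyls, load_structure
from .tensor import ChiTensor

__all__ = ["SimulationConfig", "make_bundle", "write_bundle_pdb", "simulate_datasets", "SimulatedRun"]

# default (1H, 13C) base-shift windows per residue type, ppm — deliberately
# narrow to mimic the poor dispersion of aliphatic-rich helical bundles
SHIFT_WINDOWS = {
    "ILE": ((0.5, 1.0), (9.0, 15.0)),
    "LEU": ((0.6, 1.0), (22.0, 27.0)),
    "VAL": ((0.7, 1.1), (19.0, 24.0)),
    "MET": ((1.6, 2.2), (15.0, 19.0)),
}

# tensor magnitude windows per lanthanide, 1e-32 m3; Dy large and negative,
# Yb smaller and of opposite sign, as for DOTA-based tags
TENSOR_RANGES = {
    "Dy": ((-30.0, -20.0), (-6.0, -1.5)),
    "Yb": ((6.0, 10.0), (1.0, 3.0)),
}


@dataclass
class SimulationConfig:
    n_helices: int = 4
    residues_per_helix: int = 60
    bundle_radius: float = 8.0  # Å, helix axes on a circle of this radius
    tag_sites: tuple = ("B:12", "D:40")  # chain:resnum of the cysteine mutants
    lanthanides: tuple = (("B:12", "Dy"), ("D:40", "Dy"), ("B:12", "Yb"))
    noise_h: float = 0.008  # ppm
    noise_c: float = 0.05  # ppm
    blanking_radius: dict = field(default_factory=lambda: {"Dy": 20.0, "Yb": 9.0})
    metal_offset: float = 8.0  # Å from the tagged residue's Cβ, outward
    nuisance_fraction: float = 0.1
    stereospecific: dict = field(default_factory=dict)  # dataset_id -> "pro-R"/"pro-S"
    # additional samples with stereospecifically labeled Leu/Val methyls
    # (one per labeled subunit per entry), used to tell pro-R from pro-S
    # cross-peaks: (tag site, lanthanide, labeled prochirality)
    stereospecific_datasets: tuple = (("B:12", "Dy", "pro-S"),)
    shift_windows: dict = field(default_factory=lambda: dict(SHIFT_WINDOWS))
    tensor_ranges: dict = field(default_factory=lambda: dict(TENSOR_RANGES))
    yb_h_only: bool = True  # Yb datasets measure only 1H PCSs
    seed: int = 0

    def __post_init__(self):
        if self.noise_h < 0 or self.noise_c < 0:
            raise ValueError("noise must be non-negative")
        if any(r < 0 for r in self.blanking_radius.values()):
            raise ValueError("blanking radii must be non-negative")


# ---------------------------------------------------------------------------
# idealized bundle geometry

_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = np.deg2rad(100.0)  # per residue
_CA_RADIUS = 2.3  # Å
_CH_BOND = 1.09  # Å
_TETRA = np.deg2rad(180.0 - 109.47)  # cone half-angle of methyl H about the C3 axis


def default_sequence(n: int) -> list:
    """Residue types for one helix: Leu/Val every 5th position (alternating),
    exactly one Ile and one Met, Ala elsewhere — echoing the sparse Ile/Met
    content of coiled-coil motifs."""
    seq = ["ALA"] * n
    for i in range(n):
        if i % 5 == 2:
            seq[i] = "LEU" if (i // 5) % 2 == 0 else "VAL"
    i_ile = max(int(round(0.25 * n)), 0)
    i_met = min(int(round(0.70 * n)), n - 1)
    seq[i_ile] = "ILE"
    seq[i_met] = "MET"
    return seq


def _helix_point(center, phase0, i_frac):
    ang = phase0 + i_frac * _HELIX_TWIST
    return np.array(
        [
            center[0] + _CA_RADIUS * np.cos(ang),
            center[1] + _CA_RADIUS * np.sin(ang),
            i_frac * _HELIX_RISE,
        ]
    )


def _methyl_protons(cpos, axis):
    """Three protons at ideal tetrahedral geometry about the methyl C3 axis."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    out = []
    for k in range(3):
        psi = 2 * np.pi * k / 3
        d = np.cos(_TETRA) * axis + np.sin(_TETRA) * (np.cos(psi) * e1 + np.sin(psi) * e2)
        out.append(cpos + _CH_BOND * d)
    return out


def make_bundle(config: SimulationConfig):
    """Build an idealized parallel helix bundle as a list of PDB atom tuples.

    Each helix is an ideal α-helix (1.5 Å rise, 100°/residue) with side-chain
    methyls at ideal geometry pointing away from the bundle axis.  Returns
    (atoms, sequence) where atoms are (chain, resnum, resname, atname, xyz).
    Raises if backbone atoms approach within 1 Å.
    """
    if config.n_helices < 1:
        raise ValueError("need at least one helix")
    seq = default_sequence(config.residues_per_helix)
    chains = [chr(ord("A") + k) for k in range(config.n_helices)]
    atoms = []
    backbone = []
    for k, chain in enumerate(chains):
        ang = 2 * np.pi * k / config.n_helices
        center = (
            np.array([config.bundle_radius * np.cos(ang), config.bundle_radius * np.sin(ang)])
            if config.n_helices > 1
            else np.zeros(2)
        )
        phase0 = ang + np.pi / 4  # deterministic per-helix phase
        for i, resname in enumerate(seq):
            resnum = i + 1
            ca = _helix_point(center, phase0, i)
            n = _helix_point(center, phase0, i - 0.35)
            c = _helix_point(center, phase0, i + 0.35)
            out_xy = ca[:2] - (center if config.n_helices > 1 else ca[:2] * 0)
            nrm = np.linalg.norm(out_xy)
            u = np.array([out_xy[0], out_xy[1], 0.0]) / (nrm if nrm > 0 else 1.0)
            o = c + 1.23 * u
            for name, pos in (("N", n), ("CA", ca), ("C", c), ("O", o)):
                atoms.append((chain, resnum, resname, name, tuple(pos)))
                if name in ("N", "CA", "C"):
                    backbone.append(pos)
            # outward direction from the *bundle* axis so tags sit outside
            gout_xy = ca[:2]
            gn = np.linalg.norm(gout_xy)
            g = np.array([gout_xy[0], gout_xy[1], 0.0]) / (gn if gn > 0 else 1.0)
            t = np.cross(np.array([0.0, 0.0, 1.0]), g)
            cb = ca + 1.53 * g + 0.3 * np.array([0, 0, 1])
            atoms.append((chain, resnum, resname, "CB", tuple(cb)))
            if resname == "ALA":
                continue
            methyl_pos = {}
            if resname == "ILE":
                methyl_pos["CD1"] = cb + 2.5 * g + 0.4 * t
            elif resname == "MET":
                methyl_pos["CE"] = cb + 2.8 * g - 0.3 * t
            elif resname == "LEU":
                cg = cb + 1.5 * g
                atoms.append((chain, resnum, resname, "CG", tuple(cg)))
                methyl_pos["CD1"] = cg + 1.0 * g + 1.25 * t
                methyl_pos["CD2"] = cg + 1.0 * g - 1.25 * t
            elif resname == "VAL":
                methyl_pos["CG1"] = cb + 1.0 * g + 1.25 * t
                methyl_pos["CG2"] = cb + 1.0 * g - 1.25 * t
            for cname, cpos in methyl_pos.items():
                atoms.append((chain, resnum, resname, cname, tuple(cpos)))
                axis = cpos - cb
                for hidx, hpos in enumerate(_methyl_protons(cpos, axis), start=1):
                    atoms.append(
                        (chain, resnum, resname, f"H{cname[1:]}{hidx}", tuple(hpos))
                    )
    bb = np.array(backbone)
    tree = cKDTree(bb)
    close = tree.query_pairs(1.0)
    if close:
        raise ValueError("backbone atoms overlap below 1 Å; adjust bundle geometry")
    return atoms, seq


def write_bundle_pdb(atoms, path) -> None:
    """Write atom tuples as a single-model PDB file (deterministic bytes)."""
    with open(path, "w") as fh:
        serial = 1
        for chain, resnum, resname, name, (x, y, z) in atoms:
            elem = name[0] if name[0] in "HNCO" else name[0]
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                f"ATOM  {serial:5d} {pad_name}{'':1s}{resname:>3s} {chain}{resnum:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}\n"
            )
            serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# dataset simulation


@dataclass
class SimulatedRun:
    structure: StructureModel
    methyls: list
    datasets: list
    tensors: dict  # (site, lanthanide) -> true ChiTensor
    truth: dict  # dataset_id -> {untagged peak id: methyl id}
    blanked_truth: dict  # dataset_id -> set of methyl ids blanked
    true_pcs: dict  # dataset_id -> {(peak id, nucleus): noiseless PCS}
    base_shifts: dict  # (subunit, methyl id) -> (1H, 13C)
    tag_positions: dict  # (site, lanthanide) -> Cβ position of tagged residue
    free_reference: dict  # subunit -> list of Peak (free-subunit spectrum)
    config: SimulationConfig = None


def _random_tensor(rng, lanthanide, metal, ranges):
    (ax_lo, ax_hi), (rh_lo, rh_hi) = ranges[lanthanide]
    ax = rng.uniform(ax_lo, ax_hi)
    rh = rng.uniform(rh_lo, rh_hi)
    # enforce the UTR bound so the drawn parameters are already canonical-scale
    rh = np.clip(rh, -2 * abs(ax) / 3, 2 * abs(ax) / 3)
    axes = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return ChiTensor(float(ax), float(rh), metal, axes, lanthanide=lanthanide)


def simulate_datasets(structure: StructureModel, config: SimulationConfig) -> SimulatedRun:
    """Simulate paired peak lists for every (labeled subunit × site ×
    lanthanide) combination, with full ground truth.

    The untagged peak of each methyl sits at a base shift drawn uniformly in
    its residue type's window.  The tagged peak adds the forward-model PCS
    (¹H at the proton centroid, ¹³C at the carbon) plus Gaussian noise, and is
    removed entirely when the methyl carbon lies within the lanthanide's
    blanking radius of the metal.  Nuisance peaks (unassembled subunit)
    appear at independent shifts in both lists, sharp and PCS-free.
    """
    rng = np.random.default_rng(config.seed)
    methyls = extract_methyls(structure)
    by_subunit = {}
    for m in methyls:
        by_subunit.setdefault(m.subunit, []).append(m)
    subunits = sorted(by_subunit)

    # experiment schedule: plain samples plus stereospecific companions
    schedule = [(site, lan, None) for site, lan in config.lanthanides]
    schedule += [tuple(entry) for entry in config.stereospecific_datasets]

    # --- true tensors, one per (site, lanthanide)
    tensors, tag_positions = {}, {}
    for site, lanthanide in dict.fromkeys((s, l) for s, l, _ in schedule):
        chain, resnum = site.split(":")
        cb = structure.get_atom(chain, int(resnum), "CB")
        if cb is None:
            raise ValueError(f"tag site {site} has no CB atom in the structure")
        cbpos = np.array(cb.xyz)
        out = cbpos - np.array([0.0, 0.0, cbpos[2]])
        nrm = np.linalg.norm(out)
        u = out / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        metal = cbpos + config.metal_offset * u
        t = _random_tensor(rng, lanthanide, metal, config.tensor_ranges)
        tensors[(site, lanthanide)] = ChiTensor(
            t.dchi_ax, t.dchi_rh, t.metal, t.axes, lanthanide=lanthanide, site=site
        )
        tag_positions[(site, lanthanide)] = cbpos

    # --- base shifts per methyl (shared across that subunit's datasets)
    base_shifts = {}
    for subunit in subunits:
        for m in sorted(by_subunit[subunit], key=lambda m: m.methyl_id):
            (h0, h1), (c0, c1) = config.shift_windows[m.restype]
            base_shifts[(subunit, m.methyl_id)] = (
                float(rng.uniform(h0, h1)),
                float(rng.uniform(c0, c1)),
            )

    # --- free-subunit reference spectra and nuisance choices
    free_reference, nuisance_sets = {}, {}
    for subunit in subunits:
        ms = sorted(by_subunit[subunit], key=lambda m: m.methyl_id)
        n_nuis = int(round(config.nuisance_fraction * len(ms)))
        chosen = (
            list(rng.choice(len(ms), size=n_nuis, replace=False)) if n_nuis else []
        )
        ref = []
        for k, idx in enumerate(sorted(chosen)):
            m = ms[idx]
            h, c = base_shifts[(subunit, m.methyl_id)]
            # the free subunit is unfolded: shifts nearby but not identical
            ref.append(
                Peak(
                    f"free_{subunit}_{k + 1:02d}",
                    h + float(rng.normal(0, 0.03)),
                    c + float(rng.normal(0, 0.2)),
                    intensity=5.0,
                    origin="nuisance",
                )
            )
        free_reference[subunit] = ref
        nuisance_sets[subunit] = ref

    datasets, truth, blanked_truth, true_pcs = [], {}, {}, {}
    for subunit in subunits:
        for site, lanthanide, sched_stereo in schedule:
            ds_id = f"{subunit}_{site.replace(':', '')}{lanthanide}"
            if sched_stereo:
                ds_id += "_" + sched_stereo.replace("-", "")
            nuclei = ("H",) if (lanthanide == "Yb" and config.yb_h_only) else ("H", "C")
            stereo = config.stereospecific.get(ds_id, sched_stereo)
            tensor = tensors[(site, lanthanide)]
            radius = config.blanking_radius.get(lanthanide, 0.0)
            ms = sorted(by_subunit[subunit], key=lambda m: m.methyl_id)
            if stereo:
                ms = [m for m in ms if m.stereo in ("none", stereo)]
            untagged, tagged = [], []
            ds_truth, ds_true_pcs = {}, {}
            ds_blanked = set()
            for i, m in enumerate(ms):
                h, c = base_shifts[(subunit, m.methyl_id)]
                pid = f"u{i + 1:03d}"
                untagged.append(Peak(pid, h, c, intensity=1.0, origin="complex"))
                ds_truth[pid] = m.methyl_id
                from .tensor import pcs_forward

                pcs_h = pcs_forward(tensor, m.proton_position)
                pcs_c = pcs_forward(tensor, m.carbon_position)
                ds_true_pcs[(pid, "H")] = pcs_h
                ds_true_pcs[(pid, "C")] = pcs_c
                dist = np.linalg.norm(m.carbon_position - tensor.metal)
                if dist <= radius:
                    ds_blanked.add(m.methyl_id)
                    continue
                tagged.append(
                    Peak(
                        f"t{i + 1:03d}",
                        h + pcs_h + float(rng.normal(0, config.noise_h)),
                        c + pcs_c + float(rng.normal(0, config.noise_c)),
                        intensity=1.0,
                        origin="complex",
                    )
                )
            # nuisance peaks: same (free-subunit) position in both spectra
            for k, p in enumerate(nuisance_sets[subunit]):
                pid = f"n{k + 1:03d}"
                untagged.append(Peak(pid, p.h_ppm, p.c_ppm, 5.0, origin="nuisance"))
                tagged.append(
                    Peak(
                        f"nt{k + 1:03d}",
                        p.h_ppm + float(rng.normal(0, config.noise_h)),
                        p.c_ppm + float(rng.normal(0, config.noise_c)),
                        5.0,
                        origin="nuisance",
                    )
                )
            datasets.append(
                Dataset(
                    dataset_id=ds_id,
                    tag_site=site,
                    lanthanide=lanthanide,
                    labeled_subunit=subunit,
                    nuclei=nuclei,
                    tagged_peaks=tagged,
                    untagged_peaks=untagged,
                    stereospecific=stereo,
                )
            )
            truth[ds_id] = ds_truth
            blanked_truth[ds_id] = ds_blanked
            true_pcs[ds_id] = ds_true_pcs

    return SimulatedRun(
        structure=structure,
        methyls=methyls,
        datasets=datasets,
        tensors=tensors,
        truth=truth,
        blanked_truth=blanked_truth,
        true_pcs=true_pcs,
        base_shifts=base_shifts,
        tag_positions=tag_positions,
        free_reference=free_reference,
        config=config,
    )


def simulate_run(config: SimulationConfig):
    """Convenience: build the bundle and simulate datasets in one call."""
    import io
    import tempfile

    atoms, _ = make_bundle(config)
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        path = fh.name
    write_bundle_pdb(atoms, path)
    structure = load_structure(path)
    Path(path).unlink()
    return simulate_datasets(structure, config)


def write_run(run: SimulatedRun, outdir) -> None:
    """Write the run as text files: PDB, peak-list TSVs, ground-truth TSVs
    and a manifest, under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # structure (re-written from the model for self-containment)
    atoms = [(a.chain, a.resnum, a.resname, a.name, a.xyz) for a in run.structure.atoms]
    write_bundle_pdb(atoms, outdir / "structure.pdb")
    manifest = [f"seed\t{run.config.seed}" if run.config else "seed\t?"]
    for ds in run.datasets:
        write_peaklist(ds.tagged_peaks, outdir / f"{ds.dataset_id}_tagged.tsv")
        write_peaklist(ds.untagged_peaks, outdir / f"{ds.dataset_id}_untagged.tsv")
        with open(outdir / f"{ds.dataset_id}_truth.tsv", "w") as fh:
            fh.write("peak_id\tmethyl_id\n")
            for pid, mid in sorted(run.truth[ds.dataset_id].items()):
                fh.write(f"{pid}\t{mid}\n")
        manifest.append(
            f"dataset\t{ds.dataset_id}\t{ds.tag_site}\t{ds.lanthanide}\t{ds.labeled_subunit}"
        )
    with open(outdir / "tensors_truth.tsv", "w") as fh:
        fh.write("site\tlanthanide\tdchi_ax\tdchi_rh\tx\ty\tz\n")
        for (site, lan), t in sorted(run.tensors.items()):
            fh.write(
                f"{site}\t{lan}\t{t.dchi_ax:.4f}\t{t.dchi_rh:.4f}\t"
                + "\t".join(f"{v:.3f}" for v in t.metal)
                + "\n"
            )
    (outdir / "manifest.tsv").write_text("\n".join(manifest) + "\n")
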