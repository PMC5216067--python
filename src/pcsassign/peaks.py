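"""Peak lists and PCS measurement.

A PCS is measured as the chemical-shift difference of the same cross-peak
between the paramagnetic (tagged) and diamagnetic (untagged) spectrum:

    PCS = δ(tagged) − δ(untagged)

Removal of the lanthanide tag by reduction is the diamagnetic reference.
Cross-peaks of methyls close to a strongly paramagnetic lanthanide are
broadened beyond detection ("blanked"): the untagged peak then has no partner
in the tagged list, which is itself information the assignment stage uses.

Peak pairing between the two spectra is solved as a one-to-one linear
assignment problem minimizing the total tolerance-weighted displacement,
subject to per-nucleus displacement windows.  Default measurement precisions
are 0.008 ppm for ¹H and 0.05 ppm for ¹³C.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Peak",
    "PCSRecord",
    "Dataset",
    "read_peaklist",
    "write_peaklist",
    "pair_peaks",
    "compute_pcs",
    "read_npc",
    "write_npc",
    "default_tolerance",
    "TOLERANCE_H",
    "TOLERANCE_C",
]

TOLERANCE_H = 0.008  # ppm, 1H PCS precision
TOLERANCE_C = 0.05  # ppm, 13C PCS precision


def default_tolerance(nucleus: str) -> float:
    if nucleus == "H":
        return TOLERANCE_H
    if nucleus == "C":
        return TOLERANCE_C
    raise ValueError(f"unknown nucleus {nucleus!r}")


@dataclass(frozen=True)
class Peak:
    """One ¹H-¹³C cross-peak."""

    peak_id: str
    h_ppm: float
    c_ppm: float
    intensity: float = 1.0
    origin: str = "unknown"  # complex / nuisance / unknown

    def __post_init__(self):
        if not (np.isfinite(self.h_ppm) and np.isfinite(self.c_ppm)):
            raise ValueError(f"peak {self.peak_id}: non-finite shift")


@dataclass(frozen=True)
class PCSRecord:
    """One measured, blanked or predicted PCS for one nucleus.

    ``value`` is in ppm; blanked records (peak broadened beyond detection in
    the tagged spectrum) carry ``value=None``.
    """

    dataset_id: str
    peak_id: str | None
    nucleus: str  # H or C
    value: float | None
    tolerance: float
    status: str = "measured"  # measured / blanked / predicted
    methyl_id: str | None = None

    def __post_init__(self):
        if self.nucleus not in ("H", "C"):
            raise ValueError(f"unknown nucleus {self.nucleus!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.status == "blanked" and self.value is not None:
            raise ValueError("blanked records carry no value")

    def with_methyl(self, methyl_id: str) -> "PCSRecord":
        return replace(self, methyl_id=methyl_id)


@dataclass
class Dataset:
    """One (labeled subunit, tag site, lanthanide) experiment.

    ``tag_site`` is ``chain:resnum`` of the cysteine mutant carrying the tag.
    ``nuclei`` lists the nuclei whose PCSs are used (e.g. Yb datasets are
    commonly ¹H-only because the smaller shifts approach the ¹³C precision).
    """

    dataset_id: str
    tag_site: str
    lanthanide: str
    labeled_subunit: str
    nuclei: tuple = ("H", "C")
    condition: str = ""
    tagged_peaks: list = field(default_factory=list)
    untagged_peaks: list = field(default_factory=list)
    stereospecific: str | None = None  # None, "pro-R" or "pro-S"

    def __post_init__(self):
        if not self.nuclei:
            raise ValueError("dataset must use at least one nucleus")

    @property
    def group(self) -> tuple:
        """Tensor-fit group key: datasets sharing tag site and lanthanide are
        pooled into one tensor with a common metal position."""
        return (self.tag_site, self.lanthanide)


# ---------------------------------------------------------------------------
# peak-list I/O (tab-separated text with header: id, 1H_ppm, 13C_ppm, intensity)

PEAKLIST_COLUMNS = ["id", "1H_ppm", "13C_ppm", "intensity"]


def read_peaklist(path) -> list:
    path = Path(path)
    peaks = []
    seen = set()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != PEAKLIST_COLUMNS[:3]:
            raise ValueError(f"{path}: missing peak-list header {PEAKLIST_COLUMNS[:3]}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                pid = row[0].strip()
                h, c = float(row[1]), float(row[2])
                inten = float(row[3]) if len(row) > 3 and row[3].strip() else 1.0
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from exc
            if pid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate peak id {pid!r}")
            seen.add(pid)
            peaks.append(Peak(pid, h, c, inten))
    return peaks


def write_peaklist(peaks, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PEAKLIST_COLUMNS) + "\n")
        for p in peaks:
            fh.write(f"{p.peak_id}\t{p.h_ppm:.6f}\t{p.c_ppm:.6f}\t{p.intensity:.6g}\n")


# ---------------------------------------------------------------------------
# pairing


@dataclass
class Pairing:
    """Result of matching tagged against untagged peaks.

    ``ambiguous_untagged`` holds untagged peaks whose best pairing could not
    be distinguished from an alternative (crossing diagonal trajectories);
    they carry no measured PCS but are *not* blanked-beyond-detection
    candidates either.
    """

    pairs: list  # (untagged Peak, tagged Peak)
    unmatched_untagged: list  # blanked candidates
    unmatched_tagged: list
    ambiguous_untagged: list = field(default_factory=list)
    ambiguous_tagged: list = field(default_factory=list)


def pair_peaks(
    tagged,
    untagged,
    max_shift=(2.0, 2.0),
    tol=(TOLERANCE_H, TOLERANCE_C),
    ambiguity_margin: float | None = None,
) -> Pairing:
    """One-to-one pairing of tagged vs untagged peaks.

    A pseudocontact shift in ppm is the same for every nucleus at (nearly)
    the same position, so a genuine tagged↔untagged pair of one methyl moves
    along the spectral diagonal: Δδ(¹H) ≈ Δδ(¹³C) in ppm, up to the
    measurement noise and the small ¹H/¹³C evaluation-point difference.  The
    pairing therefore minimizes the total *deviation from the diagonal*
    (normalized by the combined tolerance plus a proportional term for the
    proton/carbon geometry difference), with a mild preference for smaller
    displacements to break ties among diagonal candidates, subject to the
    per-nucleus windows ``max_shift`` (ppm).  Untagged peaks without a
    partner are returned as candidates for paramagnetic blanking.  Ties are
    broken by intensity similarity, then by lowest peak id, so the result is
    deterministic.
    """
    if not tagged or not untagged:
        return Pairing([], list(untagged), list(tagged))
    max_h, max_c = max_shift
    tol_h, tol_c = tol
    nu, nt = len(untagged), len(tagged)
    big = 1e12
    cost = np.full((nu, nt), big)
    tagged_order = {p.peak_id: k for k, p in enumerate(sorted(tagged, key=lambda p: p.peak_id))}
    for i, u in enumerate(untagged):
        for j, t in enumerate(tagged):
            dh, dc = t.h_ppm - u.h_ppm, t.c_ppm - u.c_ppm
            if abs(dh) > max_h or abs(dc) > max_c:
                continue
            shift = max(abs(dh), abs(dc))
            sigma2 = tol_h**2 + tol_c**2 + (0.06 * shift) ** 2
            diag2 = (dh - dc) ** 2 / sigma2
            if diag2 > 25.0:  # >5σ off the diagonal: not a PCS displacement
                continue
            c = diag2
            c += 0.1 * ((dh / max_h) ** 2 + (dc / max_c) ** 2)
            # deterministic tie-breaks, small enough not to perturb real costs
            c += 1e-9 * abs(t.intensity - u.intensity)
            c += 1e-12 * tagged_order[t.peak_id]
            cost[i, j] = c
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    ambiguous_u, ambiguous_t = [], []
    used_u, used_t = set(), set()
    for i, j in zip(rows, cols):
        if cost[i, j] >= big:
            continue
        used_u.add(i)
        used_t.add(j)
        if ambiguity_margin is not None:
            # the pair is trusted only if no rival pairing comes close
            alt_t = np.delete(cost[i, :], j)
            alt_u = np.delete(cost[:, j], i)
            rival = min(
                alt_t.min() if alt_t.size else np.inf,
                alt_u.min() if alt_u.size else np.inf,
            )
            if rival - cost[i, j] < ambiguity_margin:
                ambiguous_u.append(untagged[i])
                ambiguous_t.append(tagged[j])
                continue
        pairs.append((untagged[i], tagged[j]))
    unmatched_u = [u for i, u in enumerate(untagged) if i not in used_u]
    unmatched_t = [t for j, t in enumerate(tagged) if j not in used_t]
    return Pairing(pairs, unmatched_u, unmatched_t, ambiguous_u, ambiguous_t)


def compute_pcs(pairing: Pairing, dataset: Dataset, tolerances=None) -> list:
    """PCS records from a pairing: value = δ(tagged) − δ(untagged) per nucleus
    in ``dataset.nuclei``; unmatched untagged peaks become blanked records."""
    tolerances = tolerances or {"H": TOLERANCE_H, "C": TOLERANCE_C}
    records = []
    for u, t in pairing.pairs:
        for nuc in dataset.nuclei:
            delta = (t.h_ppm - u.h_ppm) if nuc == "H" else (t.c_ppm - u.c_ppm)
            records.append(
                PCSRecord(
                    dataset_id=dataset.dataset_id,
                    peak_id=u.peak_id,
                    nucleus=nuc,
                    value=delta,
                    tolerance=tolerances[nuc],
                    status="measured",
                )
            )
    for u in pairing.unmatched_untagged:
        for nuc in dataset.nuclei:
            records.append(
                PCSRecord(
                    dataset_id=dataset.dataset_id,
                    peak_id=u.peak_id,
                    nucleus=nuc,
                    value=None,
                    tolerance=tolerances[nuc],
                    status="blanked",
                )
            )
    return records


# ---------------------------------------------------------------------------
# NPC-style PCS interchange format
#
# Whitespace-separated "residue atom value tolerance", one record per line,
# with a chain-prefix extension: residue is "CHAIN:RESNUM".  Methyl protons
# use the pseudoatom names QD1/QD2/QE/QG1/QG2; carbons use CD1/CD2/CE/CG1/CG2.

_METHYL_TO_ATOM = {
    ("d1", "C"): "CD1",
    ("d2", "C"): "CD2",
    ("e", "C"): "CE",
    ("g1", "C"): "CG1",
    ("g2", "C"): "CG2",
    ("d1", "H"): "QD1",
    ("d2", "H"): "QD2",
    ("e", "H"): "QE",
    ("g1", "H"): "QG1",
    ("g2", "H"): "QG2",
}
_ATOM_TO_METHYL = {v: k for k, v in _METHYL_TO_ATOM.items()}


def write_npc(records, path, dataset_id: str = "") -> None:
    """Write assigned, measured PCS records in NPC-style tabular text.

    Records must carry ``methyl_id`` (``chain:resnum:label``); blanked and
    unassigned records are not representable in this format and are skipped.
    """
    with open(path, "w") as fh:
        fh.write("# chain:residue atom pcs_ppm tolerance_ppm\n")
        for r in records:
            if r.methyl_id is None or r.value is None:
                continue
            chain, resnum, label = r.methyl_id.split(":")
            atom = _METHYL_TO_ATOM[(label, r.nucleus)]
            fh.write(f"{chain}:{resnum} {atom} {r.value:.6f} {r.tolerance:.6f}\n")


def read_npc(path, dataset_id: str = "") -> list:
    """Read an NPC-style PCS file into measured records with methyl ids."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                resspec, atom, value, tol = parts
                chain, resnum = resspec.split(":")
                label, nucleus = _ATOM_TO_METHYL[atom]
                records.append(
                    PCSRecord(
                        dataset_id=dataset_id,
                        peak_id=None,
                        nucleus=nucleus,
                        value=float(value),
                        tolerance=float(tol),
                        status="measured",
                        methyl_id=f"{chain}:{int(resnum)}:{label}",
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line {line!r}") from exc
    return records
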