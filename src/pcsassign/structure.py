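"""Structure handling: PDB parsing and extraction of ILMV methyl reporters.

The assignment approach works on the Ile-δ1, Leu-δ1/δ2, Met-ε and Val-γ1/γ2
methyl groups of a protein (complex) of known structure.  Each methyl
contributes one ¹H-¹³C cross-peak; the forward model needs one evaluation
point per nucleus: the methyl carbon for ¹³C and, for ¹H, the centroid of the
three methyl protons (fast rotation about the threefold axis averages the
proton positions onto it).  Structures without protons are accepted — ¹H PCSs
are then evaluated at the carbon, which is a ≤0.37 Å approximation, and a
warning is logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "MethylGroup",
    "load_structure",
    "extract_methyls",
    "METHYL_CARBONS",
    "STEREO_CONVENTION",
]

# residue type -> {methyl carbon atom name: greek methyl label}
METHYL_CARBONS = {
    "ILE": {"CD1": "d1"},
    "LEU": {"CD1": "d1", "CD2": "d2"},
    "MET": {"CE": "e"},
    "VAL": {"CG1": "g1", "CG2": "g2"},
}

# Prochirality convention for the two methyls of Leu and Val.  The δ/γ
# numbering ↔ pro-R/pro-S correspondence is a convention, not a fact of the
# data; override this mapping if your naming differs.
STEREO_CONVENTION = {
    ("LEU", "d1"): "pro-R",
    ("LEU", "d2"): "pro-S",
    ("VAL", "g1"): "pro-R",
    ("VAL", "g2"): "pro-S",
}


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    xyz: tuple


@dataclass
class StructureModel:
    """Atoms of one model of a structure, heteroatoms and waters excluded."""

    atoms: list
    model_index: int = 0

    def __post_init__(self):
        index = {}
        for a in self.atoms:
            key = (a.chain, a.resnum, a.name)
            if key not in index:  # keep first altloc only
                index[key] = a
        self._index = index

    def get_atom(self, chain: str, resnum: int, name: str):
        return self._index.get((chain, resnum, name))

    def chains(self):
        return sorted({a.chain for a in self.atoms})

    def residues(self, chain=None):
        """Sorted (chain, resnum, resname) triples."""
        seen = {}
        for a in self.atoms:
            if chain is None or a.chain == chain:
                seen.setdefault((a.chain, a.resnum), a.resname)
        return sorted((c, r, n) for (c, r), n in seen.items())


@dataclass(frozen=True)
class MethylGroup:
    """One ¹³CH₃ reporter.

    ``methyl_id`` is the canonical ``chain:resnum:label`` key (e.g.
    ``"A:57:d1"``) used to join records across modules.
    """

    chain: str
    resnum: int
    restype: str  # ILE / LEU / MET / VAL
    methyl: str  # d1 / d2 / e / g1 / g2
    stereo: str  # pro-R / pro-S / none
    carbon_position: np.ndarray
    proton_position: np.ndarray
    subunit: str = ""

    @property
    def methyl_id(self) -> str:
        return f"{self.chain}:{self.resnum}:{self.methyl}"

    @property
    def carbon_name(self) -> str:
        for cname, label in METHYL_CARBONS[self.restype].items():
            if label == self.methyl:
                return cname
        raise KeyError(self.methyl)


def load_structure(path, model: int = 1) -> StructureModel:
    """Read a PDB file, returning ATOM records of the selected model.

    ``model`` is the 1-based PDB MODEL number.  Heteroatoms and waters are
    excluded.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (FileNotFoundError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no ATOM records in {path}")
    st.setup_entities()
    if model < 1 or model > len(st):
        raise IndexError(f"model {model} out of range (structure has {len(st)} model(s))")
    mdl = st[model - 1]
    atoms = []
    for chain in mdl:
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            for atom in res:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                pos = (atom.pos.x, atom.pos.y, atom.pos.z)
                if not all(np.isfinite(pos)):
                    raise ValueError("non-finite coordinate in structure")
                atoms.append(Atom(chain.name, res.seqid.num, res.name, atom.name, pos))
    if not atoms:
        raise ValueError(f"no ATOM records in {path}")
    return StructureModel(atoms, model_index=model)


def parse_selection(selection: str):
    """Parse chain selections like ``"A"`` or ``"A:29-93"`` into
    (chain, lo, hi) with ``None`` bounds meaning unbounded."""
    out = []
    for part in selection.split(","):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            chain, rng = part.split(":", 1)
            lo, hi = rng.split("-", 1)
            out.append((chain, int(lo), int(hi)))
        else:
            out.append((part, None, None))
    if not out:
        raise ValueError("empty chain selection")
    return out


def _in_selection(chain, resnum, sel):
    for c, lo, hi in sel:
        if chain == c and (lo is None or lo <= resnum <= hi):
            return True
    return False


def extract_methyls(
    structure: StructureModel,
    chains: str | None = None,
    subunit_of=None,
    stereo_convention=None,
) -> list:
    """Extract ILMV methyl groups from selected chains.

    Parameters
    ----------
    chains:
        Selection string (``"A,B"`` or ``"A:29-93"``); ``None`` selects all.
    subunit_of:
        Optional mapping chain id -> subunit label.
    stereo_convention:
        Override of :data:`STEREO_CONVENTION`.

    Residues whose methyl carbon is missing are skipped with a warning.  When
    methyl protons are absent the proton reporter falls back to the carbon
    position (logged once per call).
    """
    conv = dict(STEREO_CONVENTION)
    if stereo_convention:
        conv.update(stereo_convention)
    sel = parse_selection(chains) if chains else None
    subunit_of = subunit_of or {}

    groups = []
    skipped = []
    missing_h = 0
    for chain, resnum, resname in structure.residues():
        if resname not in METHYL_CARBONS:
            continue
        if sel is not None and not _in_selection(chain, resnum, sel):
            continue
        for cname, label in METHYL_CARBONS[resname].items():
            carbon = structure.get_atom(chain, resnum, cname)
            if carbon is None:
                skipped.append((chain, resnum, cname))
                continue
            cpos = np.array(carbon.xyz)
            stem = cname[1:]  # CD1 -> D1
            hpos = []
            for i in (1, 2, 3):
                h = structure.get_atom(chain, resnum, f"H{stem}{i}")
                if h is not None:
                    hpos.append(h.xyz)
            if len(hpos) == 3:
                ppos = np.mean(hpos, axis=0)
            else:
                ppos = cpos
                missing_h += 1
            stereo = conv.get((resname, label), "none")
            groups.append(
                MethylGroup(
                    chain=chain,
                    resnum=resnum,
                    restype=resname,
                    methyl=label,
                    stereo=stereo,
                    carbon_position=cpos,
                    proton_position=np.asarray(ppos, float),
                    subunit=subunit_of.get(chain, chain),
                )
            )
    if skipped:
        warnings.warn(
            f"{len(skipped)} methyl carbon(s) missing and skipped: "
            + ", ".join(f"{c}:{r}:{n}" for c, r, n in skipped[:5])
        )
    if missing_h:
        logger.warning(
            "%d methyl(s) lack protons; 1H PCSs will be evaluated at the carbon",
            missing_h,
        )
    return groups
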