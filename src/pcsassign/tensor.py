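"""Anisotropic magnetic susceptibility (Δχ) tensors and the pseudocontact shift.

A paramagnetic lanthanide bound at a fixed site shifts the resonance of every
nearby nucleus by the pseudocontact shift (PCS).  For a point metal with an
anisotropic susceptibility tensor Δχ the PCS of a nucleus at polar coordinates
(r, θ, φ) in the tensor eigenframe is

    PCS(ppm) = 1e4 / (12 π r³) · [ Δχ_ax (3 cos²θ − 1)
                                   + 3/2 · Δχ_rh sin²θ cos 2φ ]

with r in Å and Δχ_ax, Δχ_rh in units of 1e-32 m³ (the prefactor absorbs the
unit conversions; with these units the bracket is dimensionless and the result
is directly in ppm).  Equivalently, writing the traceless symmetric tensor χ in
the molecular frame,

    PCS(ppm) = 1e4 / (4 π r⁵) · rᵀ χ r ,

which is linear in the five independent components of χ — the property the
fitting module exploits.

Conventions
-----------
* Δχ_ax = χ_zz − (χ_xx + χ_yy)/2 and Δχ_rh = χ_xx − χ_yy in the eigenframe.
* The *unique tensor representation* (UTR) orders the eigenvalues by
  increasing magnitude, |χ_xx| ≤ |χ_yy| ≤ |χ_zz|, which guarantees
  |Δχ_rh| ≤ (2/3)|Δχ_ax| and makes |Δχ_ax| maximal among the equivalent
  axis relabelings, so fitted tensors are comparable between runs.
* Orientations are stored as three orthonormal axis row-vectors (x, y, z)
  with determinant +1; ZYZ Euler angles are accepted at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChiTensor", "pcs_forward", "to_utr", "predict_dataset", "PCS_PREFACTOR"]

#: 1e4 / (4π): converts rᵀχr / r⁵ (Å, 1e-32 m³) to ppm.
PCS_PREFACTOR = 1.0e4 / (4.0 * np.pi)


def euler_zyz_to_axes(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix (rows = tensor x/y/z axes) from ZYZ Euler angles in rad."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    # R = Rz(alpha) @ Ry(beta) @ Rz(gamma); rows map molecular -> eigenframe
    r = np.array(
        [
            [ca * cb * cg - sa * sg, sa * cb * cg + ca * sg, -sb * cg],
            [-ca * cb * sg - sa * cg, -sa * cb * sg + ca * cg, sb * sg],
            [ca * sb, sa * sb, cb],
        ]
    )
    return r


@dataclass(frozen=True)
class ChiTensor:
    """Δχ tensor of a lanthanide site.

    Parameters
    ----------
    dchi_ax, dchi_rh:
        Axial and rhombic anisotropies in units of 1e-32 m³.
    metal:
        Metal position in Å, structure frame.
    axes:
        3×3 orthonormal matrix, rows are the tensor x-, y-, z-axes expressed
        in the structure frame (determinant +1).
    lanthanide, site:
        Free-form labels, e.g. ``"Dy"`` and ``"A:166"``.
    """

    dchi_ax: float
    dchi_rh: float
    metal: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    lanthanide: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "metal", np.asarray(self.metal, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        if self.metal.shape != (3,) or not np.all(np.isfinite(self.metal)):
            raise ValueError("metal position must be a finite 3-vector")
        a = self.axes
        if a.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix")
        if not np.allclose(a @ a.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(a) < 0:
            raise ValueError("axes must be right-handed (determinant +1)")

    @classmethod
    def from_euler(
        cls,
        dchi_ax: float,
        dchi_rh: float,
        metal,
        alpha: float,
        beta: float,
        gamma: float,
        **kwargs,
    ) -> "ChiTensor":
        """Construct from ZYZ Euler angles (radians)."""
        return cls(dchi_ax, dchi_rh, metal, euler_zyz_to_axes(alpha, beta, gamma), **kwargs)

    @property
    def eigenvalues(self) -> np.ndarray:
        """(χ_xx, χ_yy, χ_zz) in the eigenframe, traceless."""
        ax, rh = self.dchi_ax, self.dchi_rh
        return np.array([-ax / 3.0 + rh / 2.0, -ax / 3.0 - rh / 2.0, 2.0 * ax / 3.0])

    def chi_matrix(self) -> np.ndarray:
        """Traceless symmetric χ in the structure frame (1e-32 m³)."""
        return self.axes.T @ np.diag(self.eigenvalues) @ self.axes

    def is_utr(self, tol: float = 1e-9) -> bool:
        ev = np.abs(self.eigenvalues)
        return bool(ev[0] <= ev[1] + tol and ev[1] <= ev[2] + tol)


def pcs_forward(tensor: ChiTensor, point, min_r: float = 1.0):
    """Pseudocontact shift (ppm) of ``point`` (Å) under ``tensor``.

    ``point`` may be a single 3-vector or an (n, 3) array.  Raises if any
    point lies within ``min_r`` Å of the metal (the point-dipole model
    diverges there).
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    d = p - tensor.metal
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < min_r**2):
        raise ValueError("point coincides with metal (r below minimum)")
    chi = tensor.chi_matrix()
    quad = np.einsum("ij,jk,ik->i", d, chi, d)
    out = PCS_PREFACTOR * quad / r2**2.5
    return float(out[0]) if single else out


def _canonical_axes(axes: np.ndarray) -> np.ndarray:
    """Fix the sign ambiguity of eigenvectors: flip x and z so that their
    largest-magnitude component is positive, then rebuild y = z × x."""
    x, z = axes[0].copy(), axes[2].copy()
    if x[np.argmax(np.abs(x))] < 0:
        x = -x
    if z[np.argmax(np.abs(z))] < 0:
        z = -z
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def to_utr(tensor: ChiTensor) -> ChiTensor:
    """Return the equivalent tensor in the unique tensor representation.

    The returned tensor produces identical PCS values everywhere; only the
    (Δχ_ax, Δχ_rh, axes) parameterization is canonicalized.
    """
    chi = tensor.chi_matrix()
    return chi_to_tensor(
        chi, tensor.metal, lanthanide=tensor.lanthanide, site=tensor.site
    )


def chi_to_tensor(chi: np.ndarray, metal, **kwargs) -> ChiTensor:
    """Build a UTR ChiTensor from a traceless symmetric 3×3 χ matrix."""
    chi = np.asarray(chi, dtype=float)
    chi = 0.5 * (chi + chi.T)
    vals, vecs = np.linalg.eigh(chi)
    order = np.argsort(np.abs(vals))
    vals = vals[order]
    axes = _canonical_axes(vecs[:, order].T)
    dchi_ax = 1.5 * vals[2]
    dchi_rh = vals[0] - vals[1]
    return ChiTensor(dchi_ax, dchi_rh, np.asarray(metal, float), axes, **kwargs)


def predict_dataset(tensor: ChiTensor, methyls, nuclei=("H", "C")):
    """Predict PCSs for every (methyl, nucleus) combination.

    ¹H shifts are evaluated at the proton reporter position (centroid of the
    three methyl protons), ¹³C shifts at the carbon.  Returns a list of
    :class:`~pcsassign.peaks.PCSRecord` with status ``"predicted"``.
    """
    from .peaks import PCSRecord, default_tolerance

    records = []
    for nuc in nuclei:
        if nuc not in ("H", "C"):
            raise ValueError(f"unknown nucleus {nuc!r}")
    for m in methyls:
        for nuc in nuclei:
            point = m.proton_position if nuc == "H" else m.carbon_position
            records.append(
                PCSRecord(
                    dataset_id="",
                    peak_id=None,
                    methyl_id=m.methyl_id,
                    nucleus=nuc,
                    value=pcs_forward(tensor, point),
                    tolerance=default_tolerance(nuc),
                    status="predicted",
                )
            )
    return records


def format_tensor_report(tensors: dict) -> str:
    """Tabular text report of fitted tensors (one block per site/lanthanide),
    mirroring the conventional UTR listing: Δχ_ax, Δχ_rh, center, axes."""
    lines = [
        "# Dchi_ax / Dchi_rh in 1e-32 m3; center in Angstrom (structure frame);"
        " axes as unit row vectors",
    ]
    for name, t in tensors.items():
        lines.append(f"tensor\t{name}\tlanthanide={t.lanthanide}\tsite={t.site}")
        lines.append(f"dchi_ax\t{t.dchi_ax:.3f}")
        lines.append(f"dchi_rh\t{t.dchi_rh:.3f}")
        lines.append("center\t" + "\t".join(f"{v:.2f}" for v in t.metal))
        for label, vec in zip("xyz", t.axes):
            lines.append(f"axis_{label}\t" + "\t".join(f"{v:.4f}" for v in vec))
    return "\n".join(lines) + "\n"
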