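"""Per-EC luminal ATP concentration maps.

The luminal agonist field that drives the endothelium is either imported
from a per-cell file (e.g. a CFD-derived surface concentration) or
synthesised parametrically.  The surrogate emulates the structure of
CFD-derived maps on bifurcations: a high-concentration bump at the
bifurcation apex (flow stagnation at the carina), two low-concentration
wells at the lateral seams flanking the bifurcation plane (flow
detachment), and a near-uniform background elsewhere, with all values in
the physiological 0.2-1 uM range.  The seam wells shrink with bifurcation
angle, so the low-ATP area is a strictly decreasing function of the angle.
The map is steady in time: agonist boundary layers in flowing blood change
negligibly between steady state and pulsatile flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CellLattice, SurfaceMesh, cell_positions, junction_landmarks

ATP_MIN = 0.2   # uM, physiological floor of the surrogate
ATP_MAX = 1.0   # uM, physiological peak of the surrogate


class AgonistError(ValueError):
    """Raised for non-physiological parameters or invalid imported fields."""


@dataclass
class AgonistMap:
    """Per-EC luminal ATP concentration field (uM)."""

    atp: np.ndarray
    source: str = "parametric"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atp = np.asarray(self.atp, dtype=float)
        if not np.all(np.isfinite(self.atp)):
            bad = int(np.flatnonzero(~np.isfinite(self.atp))[0])
            raise AgonistError(f"non-finite ATP concentration at EC {bad}")
        if np.any(self.atp < 0):
            bad = int(np.flatnonzero(self.atp < 0)[0])
            raise AgonistError(f"negative ATP concentration at EC {bad}")

    @property
    def n_ec(self) -> int:
        return self.atp.shape[0]


def synthesize_atp_map(mesh: SurfaceMesh, lattice: CellLattice,
                       apex_level: float = 1.0, seam_level: float = 0.2,
                       background: float = 0.5,
                       apex_width: float = 0.8, seam_width: float = 1.0,
                       reference_angle: float = 80.0) -> AgonistMap:
    """Parametric surrogate ATP map on a bifurcation mesh.

    ``apex_level``, ``seam_level`` and ``background`` are concentrations in
    uM and must lie in the physiological [0.2, 1] uM window.  ``apex_width``
    and ``seam_width`` are Gaussian widths in units of the parent radius;
    the seam width is additionally scaled by ``reference_angle / angle``, so
    wider bifurcations have smaller low-ATP seam areas.
    """
    for name, val in (("apex_level", apex_level), ("seam_level", seam_level),
                      ("background", background)):
        if not ATP_MIN <= val <= ATP_MAX:
            raise AgonistError(
                f"{name} = {val} uM outside the physiological range "
                f"[{ATP_MIN}, {ATP_MAX}] uM")
    if not (seam_level <= background <= apex_level):
        raise AgonistError("levels must satisfy seam <= background <= apex")

    ec_xyz, _ = cell_positions(mesh, lattice)
    divider, saddles = junction_landmarks(mesh)
    r_p = mesh.spec.r_parent
    angle_factor = reference_angle / mesh.spec.angle_deg
    sig_a = apex_width * r_p
    sig_s = seam_width * r_p * angle_factor

    d_apex = np.min(np.linalg.norm(
        ec_xyz[:, None, :] - divider[None, :, :], axis=-1), axis=1)
    d_seam = np.min(np.linalg.norm(
        ec_xyz[:, None, :] - saddles[None, :, :], axis=-1), axis=1)

    bump = (apex_level - background) * np.exp(-0.5 * (d_apex / sig_a) ** 2)
    well = (background - seam_level) * np.exp(-0.5 * (d_seam / sig_s) ** 2)
    atp = np.clip(background + bump - well, seam_level, apex_level)
    params = dict(apex_level=apex_level, seam_level=seam_level,
                  background=background, apex_width=apex_width,
                  seam_width=seam_width, reference_angle=reference_angle,
                  angle_deg=mesh.spec.angle_deg)
    return AgonistMap(atp=atp, source="parametric", params=params)


def uniform_atp_map(n_ec: int, level: float) -> AgonistMap:
    """Spatially uniform ATP field (used for single-regime fixtures)."""
    if level < 0:
        raise AgonistError("ATP level must be >= 0")
    return AgonistMap(atp=np.full(n_ec, float(level)), source="parametric",
                      params={"uniform": level})


def seam_area(amap: AgonistMap, background: float | None = None,
              margin: float = 0.05) -> int:
    """Number of ECs in the low-ATP seam: cells below background - margin."""
    bg = background if background is not None else amap.params.get("background", 0.5)
    return int(np.count_nonzero(amap.atp < bg - margin))


def save_atp_map(amap: AgonistMap, path: str | Path) -> None:
    """Write a per-EC CSV (cell_id, atp_uM)."""
    df = pd.DataFrame({"cell_id": np.arange(amap.n_ec), "atp_uM": amap.atp})
    df.to_csv(path, index=False)


def load_atp_map(path: str | Path, lattice: CellLattice | int) -> AgonistMap:
    """Load a per-EC ATP field from CSV, validating against the lattice size."""
    n_ec = lattice if isinstance(lattice, int) else lattice.n_ec
    path = Path(path)
    if not path.exists():
        raise AgonistError(f"ATP map file not found: {path}")
    df = pd.read_csv(path)
    for colname in ("cell_id", "atp_uM"):
        if colname not in df.columns:
            raise AgonistError(f"ATP map {path} lacks required column {colname!r}")
    if len(df) != n_ec:
        raise AgonistError(
            f"ATP map {path} has {len(df)} rows but the lattice has {n_ec} ECs")
    order = np.argsort(df["cell_id"].to_numpy())
    ids = df["cell_id"].to_numpy()[order]
    if not np.array_equal(ids, np.arange(n_ec)):
        raise AgonistError(f"ATP map {path} cell_id column is not 0..{n_ec - 1}")
    atp = df["atp_uM"].to_numpy(dtype=float)[order]
    bad = np.flatnonzero(~np.isfinite(atp) | (atp < 0))
    if bad.size:
        raise AgonistError(
            f"ATP map {path}: invalid concentration {atp[bad[0]]!r} "
            f"at cell_id {int(bad[0])}")
    return AgonistMap(atp=atp, source="imported", params={"path": str(path)})
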