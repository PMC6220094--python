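"""Bifurcating arterial surface meshes and their EC/SMC cell lattices.

A bifurcation is built from three logically rectangular tubular segments
(parent, daughter 1, daughter 2), each a grid of quadrilateral *domains*
that is periodic in the circumferential direction.  The three segments are
joined watertight at the junction: the parent's terminal vertex ring is
split in half between the daughters, and the daughters share a common
flow-divider (carina) half-ring.  Daughter radii obey Murray's law
r_p^3 = r_d1^3 + r_d2^3.

Each quadrilateral domain carries a fixed cell lattice of 208 endothelial
cells (13 axial x 16 circumferential; ECs are elongated along the flow) and
80 smooth muscle cells (4 axial x 20 circumferential; SMCs wrap around the
vessel), 288 cells per domain.  Homocellular neighbourhoods are
4-connected and periodic across domain and segment boundaries;
heterocellular (myoendothelial) links are assigned by geometric overlap of
the two grids, with weights normalised to sum to one over each EC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

ECS_PER_DOMAIN = 208
SMCS_PER_DOMAIN = 80
CELLS_PER_DOMAIN = ECS_PER_DOMAIN + SMCS_PER_DOMAIN
EC_GRID = (13, 16)   # (axial, circumferential) ECs per domain
SMC_GRID = (4, 20)   # (axial, circumferential) SMCs per domain

REGIONS = ("uniform", "apex", "lateral_seam", "outer_wall", "inner_wall")
REGION_ID = {name: i for i, name in enumerate(REGIONS)}

SEGMENTS = ("parent", "daughter1", "daughter2")


class GeometryError(ValueError):
    """Raised for invalid bifurcation specifications or resolutions."""


def murray_parent_radius(r_d1: float, r_d2: float) -> float:
    """Parent radius from the daughter radii under Murray's law.

    r_p = (r_d1^3 + r_d2^3)^(1/3); radii must be non-negative and not both 0.
    """
    if r_d1 < 0 or r_d2 < 0:
        raise GeometryError("daughter radii must be >= 0")
    if r_d1 == 0 and r_d2 == 0:
        raise GeometryError("at least one daughter radius must be > 0")
    return float((r_d1**3 + r_d2**3) ** (1.0 / 3.0))


def murray_daughter_radius(r_parent: float, ratio: float = 1.0) -> tuple[float, float]:
    """Split a parent radius into two Murray-consistent daughters.

    ``ratio`` = r_d2 / r_d1; the default 1 gives symmetric daughters
    r_d = r_p / 2^(1/3).
    """
    if r_parent <= 0 or ratio <= 0:
        raise GeometryError("parent radius and daughter ratio must be > 0")
    r_d1 = r_parent / (1.0 + ratio**3) ** (1.0 / 3.0)
    return r_d1, r_d1 * ratio


@dataclass(frozen=True)
class BifurcationSpec:
    """Parametric description of a bifurcating arterial segment (mm, degrees)."""

    angle_deg: float
    r_parent: float
    r_d1: float
    r_d2: float
    segment_length: float = 9.0
    total_length: float = 18.0
    diameter: float = 2.5
    curvature: float = 0.0   # out-of-plane centreline curvature, 1/mm

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_deg < 180.0:
            raise GeometryError(f"bifurcation angle must be in (0, 180) deg, "
                                f"got {self.angle_deg}")
        for name in ("r_parent", "r_d1", "r_d2", "segment_length", "total_length",
                     "diameter"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0")
        resid = abs(self.r_parent**3 - self.r_d1**3 - self.r_d2**3) / self.r_parent**3
        if resid > 1e-9:
            raise GeometryError(
                f"radii violate Murray's law (relative residual {resid:.3e})")

    @classmethod
    def from_angle(cls, angle_deg: float, diameter: float = 2.5,
                   daughter_ratio: float = 1.0, segment_length: float = 9.0,
                   curvature: float = 0.0) -> "BifurcationSpec":
        """Spec with Murray-consistent (by default symmetric) daughters."""
        r_p = diameter / 2.0
        r_d1, r_d2 = murray_daughter_radius(r_p, daughter_ratio)
        return cls(angle_deg=angle_deg, r_parent=r_p, r_d1=r_d1, r_d2=r_d2,
                   segment_length=segment_length,
                   total_length=2.0 * segment_length, diameter=diameter,
                   curvature=curvature)


@dataclass
class SurfaceMesh:
    """Three-segment quadrilateral surface mesh of a bifurcation.

    ``vertices[s]`` has shape (A+1, C, 3) for segment ``s`` with domain grid
    (A axial x C circumferential); column index is periodic.  Domain (s, i, j)
    spans vertex rings i..i+1 and columns j..j+1 (mod C).  Global domain id =
    s*A*C + i*C + j.
    """

    spec: BifurcationSpec
    domain_grid_shape: tuple[int, int]
    vertices: list[np.ndarray]
    region_labels: np.ndarray          # (3, A, C) int, indices into REGIONS
    _neighbors: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_domains(self) -> int:
        a, c = self.domain_grid_shape
        return 3 * a * c

    def domain_id(self, seg: int, i: int, j: int) -> int:
        a, c = self.domain_grid_shape
        return seg * a * c + i * c + (j % c)

    def domain_corners(self, seg: int, i: int, j: int) -> np.ndarray:
        """The 4 corner vertices (3D, mm) of a domain, CCW."""
        v = self.vertices[seg]
        c = self.domain_grid_shape[1]
        jp = (j + 1) % c
        return np.array([v[i, j], v[i, jp], v[i + 1, jp], v[i + 1, j]])

    def domain_centers(self) -> np.ndarray:
        """(n_domains, 3) centroid per domain."""
        a, c = self.domain_grid_shape
        out = np.empty((self.n_domains, 3))
        for s in range(3):
            v = self.vertices[s]
            vp = np.roll(v, -1, axis=1)
            cent = 0.25 * (v[:-1] + vp[:-1] + v[1:] + vp[1:])
            out[s * a * c:(s + 1) * a * c] = cent.reshape(-1, 3)
        return out

    def domain_areas(self) -> np.ndarray:
        """(n_domains,) area per quadrilateral domain (mm^2, two triangles)."""
        a, c = self.domain_grid_shape
        out = np.empty(self.n_domains)
        for s in range(3):
            v = self.vertices[s]
            vp = np.roll(v, -1, axis=1)
            p00, p01 = v[:-1], vp[:-1]
            p10, p11 = v[1:], vp[1:]
            t1 = 0.5 * np.linalg.norm(np.cross(p01 - p00, p10 - p00), axis=-1)
            t2 = 0.5 * np.linalg.norm(np.cross(p01 - p11, p10 - p11), axis=-1)
            out[s * a * c:(s + 1) * a * c] = (t1 + t2).reshape(-1)
        return out

    def total_area(self) -> float:
        return float(self.domain_areas().sum())

    def domain_neighbors(self) -> np.ndarray:
        """(n_domains, 4) neighbour ids [circ-, circ+, axial-, axial+]; -1 at
        the open inlet/outlet edges."""
        if self._neighbors is not None:
            return self._neighbors
        a, c = self.domain_grid_shape
        n = self.n_domains
        nbr = np.full((n, 4), -1, dtype=np.int64)
        for s in range(3):
            ii, jj = np.meshgrid(np.arange(a), np.arange(c), indexing="ij")
            base = s * a * c + ii * c
            me = (base + jj).ravel()
            nbr[me, 0] = (base + (jj - 1) % c).ravel()
            nbr[me, 1] = (base + (jj + 1) % c).ravel()
            ax_minus = np.where(ii > 0, base - c + jj, -1)
            ax_plus = np.where(ii < a - 1, base + c + jj, -1)
            nbr[me, 2] = ax_minus.ravel()
            nbr[me, 3] = ax_plus.ravel()
        # junction: parent row a-1 <-> daughter rows 0; divider d1 <-> d2
        half = c // 2
        for j in range(c):
            pid = self.domain_id(0, a - 1, j)
            if j < half:
                did = self.domain_id(1, 0, j)          # daughter 1, aligned
            else:
                did = self.domain_id(2, 0, c - 1 - j)  # daughter 2, mirrored
            nbr[pid, 3] = did
            nbr[did, 2] = pid
        for j in range(half, c):
            d1 = self.domain_id(1, 0, j)
            d2 = self.domain_id(2, 0, j)               # shared divider columns
            nbr[d1, 2] = d2
            nbr[d2, 2] = d1
        self._neighbors = nbr
        return nbr

    def region_of_domain(self) -> np.ndarray:
        """(n_domains,) region index per domain."""
        return self.region_labels.reshape(-1)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def build_bifurcation_mesh(spec: BifurcationSpec,
                           domains: tuple[int, int] = (6, 12),
                           apex_extent: float = 0.6,
                           seam_extent: float = 1.1,
                           wall_extent: float = 0.5,
                           transition_length: float | None = None) -> SurfaceMesh:
    """Build the watertight three-segment quadrilateral surface.

    ``domains`` = (axial, circumferential) domain counts per segment; the
    circumferential count must be even and >= 4 so the junction ring can be
    split between the daughters.  ``apex_extent`` and ``seam_extent`` are
    label radii in units of the parent radius; ``wall_extent`` is the
    inner/outer-wall axial extent as a fraction of the daughter length.
    """
    a_dom, c_dom = domains
    if a_dom < 2 or c_dom < 4:
        raise GeometryError("resolution too coarse: need >= 2 x 4 domains per segment")
    if c_dom % 2:
        raise GeometryError("circumferential domain count must be even to "
                            "represent the junction apex")
    r_p, r1, r2 = spec.r_parent, spec.r_d1, spec.r_d2
    L = spec.segment_length
    theta = np.radians(spec.angle_deg)
    if transition_length is None:
        transition_length = 2.0 * r_p

    phi = -0.5 * np.pi + 2.0 * np.pi * np.arange(c_dom) / c_dom

    # parent: straight tube along +x ending at the junction plane x = 0
    x_par = np.linspace(-L, 0.0, a_dom + 1)
    par = np.empty((a_dom + 1, c_dom, 3))
    par[..., 0] = x_par[:, None]
    par[..., 1] = r_p * np.cos(phi)[None, :]
    par[..., 2] = r_p * np.sin(phi)[None, :]

    # junction ring 0 of daughter 1: parent half (columns 0..C/2) + divider
    half = c_dom // 2
    ring0 = np.empty((c_dom, 3))
    ring0[:half + 1] = par[-1, :half + 1]
    m = np.arange(1, half)
    psi = np.pi * m / half
    ring0[half + m] = np.stack([r_p * np.sin(psi), np.zeros_like(psi),
                                r_p * np.cos(psi)], axis=-1)

    def daughter(sign: float, r_d: float) -> np.ndarray:
        u = np.array([np.cos(0.5 * theta), sign * np.sin(0.5 * theta), 0.0])
        nvec = np.array([-np.sin(0.5 * theta), sign * np.cos(0.5 * theta), 0.0])
        ez = np.array([0.0, 0.0, 1.0])
        r0 = ring0.copy()
        if sign < 0:
            r0[:, 1] *= -1.0
        s = np.linspace(0.0, L, a_dom + 1)
        w = _smoothstep(s / transition_length)[:, None, None]
        circ = (s[:, None, None] * u
                + r_d * (np.cos(phi)[None, :, None] * nvec
                         + np.sin(phi)[None, :, None] * ez))
        loft = r0[None, :, :] + s[:, None, None] * u
        d = (1.0 - w) * loft + w * circ
        d[0] = r0
        return d

    d1 = daughter(+1.0, r1)
    d2 = daughter(-1.0, r2)

    # --- region labels (computed in the straight junction frame) ---
    labels = np.zeros((3, a_dom, c_dom), dtype=np.int64)
    # apex = central (downstream) portion of the divider arc; the arc's
    # endpoints are the saddle points anchoring the lateral seams
    div_cols = np.concatenate([np.arange(half, c_dom), [0]])
    psi_all = np.pi * np.arange(half + 1) / half
    central = (psi_all >= np.pi / 4 - 1e-12) & (psi_all <= 3 * np.pi / 4 + 1e-12)
    if not central.any():
        central[np.argmin(np.abs(psi_all - np.pi / 2))] = True
    divider_pts = ring0[div_cols[central]]
    saddles = np.array([[0.0, 0.0, r_p], [0.0, 0.0, -r_p]])
    verts = [par, d1, d2]
    for s_idx, v in enumerate(verts):
        vp = np.roll(v, -1, axis=1)
        cent = 0.25 * (v[:-1] + vp[:-1] + v[1:] + vp[1:])   # (A, C, 3)
        d_div = np.min(np.linalg.norm(
            cent[..., None, :] - divider_pts[None, None, :, :], axis=-1), axis=-1)
        d_sad = np.min(np.linalg.norm(
            cent[..., None, :] - saddles[None, None, :, :], axis=-1), axis=-1)
        lab = np.zeros(cent.shape[:2], dtype=np.int64)
        if s_idx > 0:
            ax_frac = (np.arange(a_dom) + 0.5)[:, None] / a_dom
            inner = np.zeros_like(lab, dtype=bool)
            inner[:, half:] = True
            near = np.broadcast_to(ax_frac < wall_extent, lab.shape)
            lab[near & inner] = REGION_ID["inner_wall"]
            lab[near & ~inner] = REGION_ID["outer_wall"]
        lab[d_sad < seam_extent * r_p] = REGION_ID["lateral_seam"]
        lab[d_div < apex_extent * r_p] = REGION_ID["apex"]
        labels[s_idx] = lab
    # guarantee resolution-independent labels for domains that touch the
    # landmarks: the divider-side first daughter rows are the apex ring,
    # and saddle-touching junction domains seed the lateral seams
    psi_dom = np.pi * (np.arange(half, c_dom) - half + 0.5) / half
    central_dom = ((psi_dom >= np.pi / 4 - 1e-9)
                   & (psi_dom <= 3 * np.pi / 4 + 1e-9))
    saddle_cols = np.unique([0, half - 1, half, c_dom - 1])
    for s_idx in (1, 2):
        row0 = labels[s_idx][0]
        for j in saddle_cols:
            if row0[j] != REGION_ID["apex"]:
                row0[j] = REGION_ID["lateral_seam"]
        row0[half:][central_dom] = REGION_ID["apex"]
    last = labels[0][a_dom - 1]
    for j in saddle_cols:
        if last[j] != REGION_ID["apex"]:
            last[j] = REGION_ID["lateral_seam"]
    if not (labels == REGION_ID["apex"]).any():
        raise GeometryError("resolution too coarse to represent the apex region")

    # --- optional out-of-plane bend about the bifurcation-plane normal ---
    if spec.curvature != 0.0:
        R = 1.0 / spec.curvature
        for v in verts:
            x, z = v[..., 0].copy(), v[..., 2].copy()
            v[..., 0] = (R + z) * np.sin(x / R)
            v[..., 2] = (R + z) * np.cos(x / R) - R

    return SurfaceMesh(spec=spec, domain_grid_shape=(a_dom, c_dom),
                       vertices=verts, region_labels=labels)


# ---------------------------------------------------------------------------
# cell lattice
# ---------------------------------------------------------------------------

@dataclass
class CellLattice:
    """EC and SMC placements with homo- and heterocellular adjacency.

    Neighbour arrays are (n, 4) and padded with the cell's own index where a
    neighbour is absent (open mesh ends), so that difference-based coupling
    contributes exactly zero there.  ``hetero_w`` is the (n_ec, n_smc) sparse
    weight matrix of myoendothelial links; each row sums to 1.
    """

    n_ec: int
    n_smc: int
    ec_neighbors: np.ndarray
    smc_neighbors: np.ndarray
    hetero_w: sparse.csr_matrix
    ec_domain: np.ndarray          # (n_ec,) domain id per EC
    smc_domain: np.ndarray         # (n_smc,) domain id per SMC
    ec_region: np.ndarray          # (n_ec,) region index per EC
    smc_region: np.ndarray
    ec_grid_pos: np.ndarray        # (n_ec, 3) = (segment, row, col) or (-1, 0, i)
    smc_grid_pos: np.ndarray
    cells_per_domain: tuple[int, int] = (ECS_PER_DOMAIN, SMCS_PER_DOMAIN)

    def __post_init__(self) -> None:
        self.hetero_w = sparse.csr_matrix(self.hetero_w)
        self.hetero_wt = sparse.csr_matrix(self.hetero_w.T)
        self.hetero_rowsum = np.asarray(self.hetero_w.sum(axis=1)).ravel()
        self.hetero_colsum = np.asarray(self.hetero_w.sum(axis=0)).ravel()

    @property
    def n_cells(self) -> int:
        return self.n_ec + self.n_smc

    def ec_cells_of_domain(self, dom: int) -> np.ndarray:
        return np.flatnonzero(self.ec_domain == dom)

    def smc_cells_of_domain(self, dom: int) -> np.ndarray:
        return np.flatnonzero(self.smc_domain == dom)


def _grid_neighbors(a_rows: int, cols: int) -> np.ndarray:
    """4-neighbourhoods of an (a_rows x cols) grid, periodic in columns,
    self-padded at the open row ends.  Returns (a_rows*cols, 4) as
    [circ-, circ+, axial-, axial+]."""
    rr, cc = np.meshgrid(np.arange(a_rows), np.arange(cols), indexing="ij")
    me = (rr * cols + cc)
    left = rr * cols + (cc - 1) % cols
    right = rr * cols + (cc + 1) % cols
    down = np.where(rr > 0, me - cols, me)
    up = np.where(rr < a_rows - 1, me + cols, me)
    return np.stack([left, right, down, up], axis=-1).reshape(-1, 4)


def _domain_hetero_pattern() -> sparse.coo_matrix:
    """Myoendothelial link weights of one domain from grid overlap.

    Both grids tile the same unit square (axial x circumferential); the link
    weight of an (EC, SMC) pair is their overlap area divided by the EC area,
    so weights over each EC sum to exactly 1.
    """
    ea, ec_ = EC_GRID
    sa, sc = SMC_GRID
    rows, cols, vals = [], [], []
    for i in range(ea):
        ax0, ax1 = i / ea, (i + 1) / ea
        for j in range(ec_):
            c0, c1 = j / ec_, (j + 1) / ec_
            e_idx = i * ec_ + j
            for a in range(int(ax0 * sa), min(sa, int(np.ceil(ax1 * sa)))):
                oa = min(ax1, (a + 1) / sa) - max(ax0, a / sa)
                if oa <= 1e-15:
                    continue
                for b in range(int(c0 * sc), min(sc, int(np.ceil(c1 * sc)))):
                    ob = min(c1, (b + 1) / sc) - max(c0, b / sc)
                    if ob <= 1e-15:
                        continue
                    rows.append(e_idx)
                    cols.append(a * sc + b)
                    vals.append(oa * ob * ea * ec_)
    return sparse.coo_matrix((vals, (rows, cols)),
                             shape=(ECS_PER_DOMAIN, SMCS_PER_DOMAIN))


def build_cell_lattice(mesh: SurfaceMesh) -> CellLattice:
    """Populate every domain of a mesh with its 208 ECs and 80 SMCs."""
    a_dom, c_dom = mesh.domain_grid_shape
    half = c_dom // 2
    region = mesh.region_of_domain()

    def layer(grid: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ga, gc = grid
        rows_seg, cols_seg = a_dom * ga, c_dom * gc
        n_seg = rows_seg * cols_seg
        nbrs, dom, pos = [], [], []
        for s in range(3):
            nb = _grid_neighbors(rows_seg, cols_seg) + s * n_seg
            rr, cc = np.meshgrid(np.arange(rows_seg), np.arange(cols_seg),
                                 indexing="ij")
            d = (s * a_dom * c_dom + (rr // ga) * c_dom + cc // gc).ravel()
            p = np.stack([np.full(n_seg, s), rr.ravel(), cc.ravel()], axis=-1)
            nbrs.append(nb)
            dom.append(d)
            pos.append(p)
        nbr = np.concatenate(nbrs)
        # junction stitching: parent top row <-> daughter bottom rows
        cols_half = half * gc
        top = (a_dom * ga - 1) * cols_seg + np.arange(cols_seg)       # parent
        d1_bot = n_seg + np.arange(cols_seg)                           # d1 row 0
        d2_bot = 2 * n_seg + np.arange(cols_seg)                       # d2 row 0
        c = np.arange(cols_seg)
        partner = np.where(c < cols_half, d1_bot[c], d2_bot[cols_seg - 1 - c])
        nbr[top, 3] = partner           # parent axial+ -> daughter
        nbr[partner, 2] = top           # daughter axial- -> parent
        # divider: d1 row0 <-> d2 row0 on the divider columns
        cd = np.arange(cols_half, cols_seg)
        nbr[d1_bot[cd], 2] = d2_bot[cd]
        nbr[d2_bot[cd], 2] = d1_bot[cd]
        return nbr, np.concatenate(dom), np.concatenate(pos)

    ec_nbr, ec_dom, ec_pos = layer(EC_GRID)
    smc_nbr, smc_dom, smc_pos = layer(SMC_GRID)
    n_ec, n_smc = ec_dom.shape[0], smc_dom.shape[0]

    pat = _domain_hetero_pattern()
    n_dom = mesh.n_domains
    # replicate the per-domain pattern with global index offsets
    ec_of_dom = np.empty((n_dom, ECS_PER_DOMAIN), dtype=np.int64)
    smc_of_dom = np.empty((n_dom, SMCS_PER_DOMAIN), dtype=np.int64)
    order_ec = np.argsort(ec_dom, kind="stable")
    order_smc = np.argsort(smc_dom, kind="stable")
    ec_of_dom[:] = order_ec.reshape(n_dom, ECS_PER_DOMAIN)
    smc_of_dom[:] = order_smc.reshape(n_dom, SMCS_PER_DOMAIN)
    # inside each domain, order cells by (local row, local col)
    ga, gc = EC_GRID
    for arr, pos, grid in ((ec_of_dom, ec_pos, EC_GRID), (smc_of_dom, smc_pos, SMC_GRID)):
        ga, gc = grid
        loc = (pos[arr, 1] % ga) * gc + pos[arr, 2] % gc
        arr[:] = np.take_along_axis(arr, np.argsort(loc, axis=1), axis=1)
    rows = ec_of_dom[:, pat.row].ravel()
    cols = smc_of_dom[:, pat.col].ravel()
    vals = np.tile(pat.data, n_dom)
    W = sparse.coo_matrix((vals, (rows, cols)), shape=(n_ec, n_smc)).tocsr()

    return CellLattice(
        n_ec=n_ec, n_smc=n_smc, ec_neighbors=ec_nbr, smc_neighbors=smc_nbr,
        hetero_w=W, ec_domain=ec_dom, smc_domain=smc_dom,
        ec_region=region[ec_dom], smc_region=region[smc_dom],
        ec_grid_pos=ec_pos, smc_grid_pos=smc_pos)


def cell_positions(mesh: SurfaceMesh, lattice: CellLattice) -> tuple[np.ndarray, np.ndarray]:
    """3D position (mm) of every EC and SMC by bilinear interpolation on its
    domain's vertex grid.  Returns ``(ec_xyz, smc_xyz)``."""

    def interp(pos: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
        ga, gc = grid
        a_dom, c_dom = mesh.domain_grid_shape
        out = np.empty((pos.shape[0], 3))
        for s in range(3):
            sel = pos[:, 0] == s
            v = mesh.vertices[s]
            fr = (pos[sel, 1] + 0.5) / ga          # vertex-ring coordinate
            fc = (pos[sel, 2] + 0.5) / gc          # vertex-column coordinate
            i0 = np.clip(fr.astype(np.int64), 0, a_dom - 1)
            tr = fr - i0
            j0 = fc.astype(np.int64) % c_dom
            tc = fc - np.floor(fc)
            j1 = (j0 + 1) % c_dom
            out[sel] = ((1 - tr)[:, None] * ((1 - tc)[:, None] * v[i0, j0]
                                             + tc[:, None] * v[i0, j1])
                        + tr[:, None] * ((1 - tc)[:, None] * v[i0 + 1, j0]
                                         + tc[:, None] * v[i0 + 1, j1]))
        return out

    return interp(lattice.ec_grid_pos, EC_GRID), interp(lattice.smc_grid_pos, SMC_GRID)


def junction_landmarks(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """(apex_points, saddle_points) of the junction, in mesh coordinates.

    The apex points sample the central (downstream-bulging) portion of the
    flow-divider half-ring shared by the daughters — the carina ridge where
    flow stagnates; the two saddle points, where all three segments meet,
    anchor the lateral seams flanking the bifurcation plane.
    """
    c = mesh.domain_grid_shape[1]
    half = c // 2
    ring0 = mesh.vertices[1][0]
    cols = np.concatenate([np.arange(half, c), [0]])
    psi = np.pi * (np.arange(half + 1)) / half
    central = (psi >= np.pi / 4 - 1e-12) & (psi <= 3 * np.pi / 4 + 1e-12)
    if not central.any():
        central[np.argmin(np.abs(psi - np.pi / 2))] = True
    apex_pts = ring0[cols[central]]
    saddles = ring0[[0, half]]
    return apex_pts, saddles


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------

@dataclass
class UnwrappedMap:
    """Flat 2D (u, v) coordinates per cell; circumferential u is periodic.

    v grows along the flow axis (parent inlet at v = 0, daughters stacked
    above the junction); the two daughters sit side by side in u.  ``ec_uv``
    and ``smc_uv`` are (n, 2) arrays in mm; ``u_period[s]`` is the
    circumferential period of segment s.
    """

    ec_uv: np.ndarray
    smc_uv: np.ndarray
    u_period: np.ndarray
    v_junction: float

    def wrap_u(self, u: np.ndarray, seg: int) -> np.ndarray:
        return np.mod(u, self.u_period[seg])


def unwrap_mesh(mesh: SurfaceMesh, lattice: CellLattice) -> UnwrappedMap:
    """Assign planar coordinates to every cell (bijective; u periodic).

    Quadrilateral widths and heights are taken from the mean 3D quad
    dimensions per segment so planar areas track surface areas.
    """
    a_dom, c_dom = mesh.domain_grid_shape
    areas = mesh.domain_areas().reshape(3, a_dom, c_dom)
    width = np.empty(3)
    height = np.empty(3)
    for s in range(3):
        v = mesh.vertices[s]
        ring_len = np.linalg.norm(np.diff(np.concatenate([v, v[:, :1]], axis=1),
                                          axis=1), axis=-1).sum(axis=1).mean()
        width[s] = ring_len / c_dom
        height[s] = areas[s].mean() / width[s]
    v_junction = a_dom * height[0]

    def uv(pos: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
        ga, gc = grid
        seg, row, col = pos[:, 0], pos[:, 1], pos[:, 2]
        du = width[seg] / gc
        dv = height[seg] / ga
        u = (col + 0.5) * du
        vv = (row + 0.5) * dv
        out = np.empty((pos.shape[0], 2))
        parent = seg == 0
        out[parent, 0] = u[parent]
        out[parent, 1] = vv[parent]
        for s in (1, 2):
            sel = seg == s
            off = 0.0 if s == 1 else width[1] * c_dom
            out[sel, 0] = u[sel] + off
            out[sel, 1] = vv[sel] + v_junction
        return out

    return UnwrappedMap(ec_uv=uv(lattice.ec_grid_pos, EC_GRID),
                        smc_uv=uv(lattice.smc_grid_pos, SMC_GRID),
                        u_period=width * c_dom, v_junction=v_junction)
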