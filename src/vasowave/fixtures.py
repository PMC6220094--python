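"""Self-contained desk-scale fixtures: cell lattices without a full mesh.

These bundles back the reference experiments and the test-suite: a single
heterocellularly coupled EC/SMC pair, 1D chains (including the classic
five-SMC synchronization scenario), and periodic quadrilateral-domain
patches with the standard 208 EC + 80 SMC per-domain lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .agonist import AgonistMap, uniform_atp_map
from .geometry import (CellLattice, EC_GRID, SMC_GRID, _domain_hetero_pattern,
                       _grid_neighbors, ECS_PER_DOMAIN, SMCS_PER_DOMAIN)

MAX_FIXTURE_DOMAINS = 16


class FixtureError(ValueError):
    pass


@dataclass
class FixtureBundle:
    lattice: CellLattice
    atp: AgonistMap
    kind: str
    extras: dict = field(default_factory=dict)


def _self_padded(n: int) -> np.ndarray:
    return np.tile(np.arange(n)[:, None], (1, 4))


def pair_lattice() -> CellLattice:
    """One EC heterocellularly linked to one SMC."""
    W = sparse.csr_matrix(np.array([[1.0]]))
    return CellLattice(
        n_ec=1, n_smc=1, ec_neighbors=_self_padded(1),
        smc_neighbors=_self_padded(1), hetero_w=W,
        ec_domain=np.zeros(1, dtype=np.int64), smc_domain=np.zeros(1, dtype=np.int64),
        ec_region=np.zeros(1, dtype=np.int64), smc_region=np.zeros(1, dtype=np.int64),
        ec_grid_pos=np.array([[-1, 0, 0]]), smc_grid_pos=np.array([[-1, 0, 0]]),
        cells_per_domain=(1, 1))


def chain_lattice(n: int, cell_type: str = "both") -> CellLattice:
    """A 1D chain: n EC/SMC pairs (``both``), or n SMCs with no endothelium
    (``smc``, the five-cell synchronization scenario)."""
    if n < 2:
        raise FixtureError("chain needs at least 2 cells")

    def line_neighbors(m: int) -> np.ndarray:
        nb = _self_padded(m)
        idx = np.arange(m)
        nb[1:, 0] = idx[:-1]
        nb[:-1, 1] = idx[1:]
        return nb

    if cell_type == "smc":
        W = sparse.csr_matrix((0, n))
        return CellLattice(
            n_ec=0, n_smc=n, ec_neighbors=np.empty((0, 4), dtype=np.int64),
            smc_neighbors=line_neighbors(n), hetero_w=W,
            ec_domain=np.empty(0, dtype=np.int64),
            smc_domain=np.zeros(n, dtype=np.int64),
            ec_region=np.empty(0, dtype=np.int64),
            smc_region=np.zeros(n, dtype=np.int64),
            ec_grid_pos=np.empty((0, 3), dtype=np.int64),
            smc_grid_pos=np.stack([np.full(n, -1), np.arange(n), np.zeros(n)], axis=-1),
            cells_per_domain=(0, n))
    if cell_type != "both":
        raise FixtureError(f"unknown chain cell_type {cell_type!r}")
    W = sparse.identity(n, format="csr")
    return CellLattice(
        n_ec=n, n_smc=n, ec_neighbors=line_neighbors(n),
        smc_neighbors=line_neighbors(n), hetero_w=W,
        ec_domain=np.arange(n), smc_domain=np.arange(n),
        ec_region=np.zeros(n, dtype=np.int64), smc_region=np.zeros(n, dtype=np.int64),
        ec_grid_pos=np.stack([np.full(n, -1), np.arange(n), np.zeros(n)], axis=-1),
        smc_grid_pos=np.stack([np.full(n, -1), np.arange(n), np.zeros(n)], axis=-1),
        cells_per_domain=(1, 1))


def patch_lattice(domains_axial: int = 1, domains_circ: int = 1) -> CellLattice:
    """A patch of quadrilateral domains with the reference 288-cell lattice.

    Periodic in the circumferential direction (as on the vessel surface),
    open at the axial ends.
    """
    n_dom = domains_axial * domains_circ
    if n_dom > MAX_FIXTURE_DOMAINS:
        raise FixtureError(
            f"{n_dom} domains exceeds the desk-scale fixture limit "
            f"({MAX_FIXTURE_DOMAINS})")

    def layer(grid):
        ga, gc = grid
        rows, cols = domains_axial * ga, domains_circ * gc
        nbr = _grid_neighbors(rows, cols)
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        dom = ((rr // ga) * domains_circ + cc // gc).ravel()
        pos = np.stack([np.zeros(rows * cols, dtype=np.int64), rr.ravel(),
                        cc.ravel()], axis=-1)
        return nbr, dom, pos

    ec_nbr, ec_dom, ec_pos = layer(EC_GRID)
    smc_nbr, smc_dom, smc_pos = layer(SMC_GRID)
    n_ec, n_smc = ec_dom.shape[0], smc_dom.shape[0]
    pat = _domain_hetero_pattern()
    ec_of_dom = np.argsort(ec_dom, kind="stable").reshape(n_dom, ECS_PER_DOMAIN)
    smc_of_dom = np.argsort(smc_dom, kind="stable").reshape(n_dom, SMCS_PER_DOMAIN)
    for arr, pos, grid in ((ec_of_dom, ec_pos, EC_GRID),
                           (smc_of_dom, smc_pos, SMC_GRID)):
        ga, gc = grid
        loc = (pos[arr, 1] % ga) * gc + pos[arr, 2] % gc
        arr[:] = np.take_along_axis(arr, np.argsort(loc, axis=1), axis=1)
    rows = ec_of_dom[:, pat.row].ravel()
    cols = smc_of_dom[:, pat.col].ravel()
    W = sparse.coo_matrix((np.tile(pat.data, n_dom), (rows, cols)),
                          shape=(n_ec, n_smc)).tocsr()
    return CellLattice(
        n_ec=n_ec, n_smc=n_smc, ec_neighbors=ec_nbr, smc_neighbors=smc_nbr,
        hetero_w=W, ec_domain=ec_dom, smc_domain=smc_dom,
        ec_region=np.zeros(n_ec, dtype=np.int64),
        smc_region=np.zeros(n_smc, dtype=np.int64),
        ec_grid_pos=ec_pos, smc_grid_pos=smc_pos)


def generate_fixture(kind: str, size: int = 1, seed: int = 0,
                     atp_level: float = 1.0,
                     atp_range: tuple[float, float] | None = None) -> FixtureBundle:
    """Build a self-contained lattice + agonist bundle.

    kind ``pair``: one EC/SMC pair (``size`` ignored); ``chain``: ``size``
    EC/SMC pairs in a line, with an ATP gradient over ``atp_range`` if
    given; ``smc_chain``: ``size`` SMCs only (synchronization scenario);
    ``patch``: ``size`` quadrilateral domains (1 x size ring), with an
    axial apex-to-seam ATP gradient if ``atp_range`` is given.
    """
    if kind == "pair":
        lat = pair_lattice()
        return FixtureBundle(lat, uniform_atp_map(1, atp_level), kind)
    if kind == "smc_chain":
        lat = chain_lattice(size, "smc")
        return FixtureBundle(lat, uniform_atp_map(0, 0.0), kind)
    if kind == "chain":
        lat = chain_lattice(size, "both")
        if atp_range is not None:
            lo, hi = atp_range
            atp = AgonistMap(np.linspace(hi, lo, size), source="parametric",
                             params={"gradient": atp_range})
        else:
            atp = uniform_atp_map(size, atp_level)
        return FixtureBundle(lat, atp, kind)
    if kind == "patch":
        lat = patch_lattice(domains_axial=size, domains_circ=1)
        if atp_range is not None:
            lo, hi = atp_range
            frac = lat.ec_grid_pos[:, 1] / max(1, lat.ec_grid_pos[:, 1].max())
            atp = AgonistMap(hi + (lo - hi) * frac, source="parametric",
                             params={"gradient": atp_range})
        else:
            atp = uniform_atp_map(lat.n_ec, atp_level)
        return FixtureBundle(lat, atp, kind)
    raise FixtureError(f"unknown fixture kind {kind!r}")
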