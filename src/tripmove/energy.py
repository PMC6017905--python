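"""Geometric clash filter and pluggable potential-energy models.

The Monte Carlo engine is decoupled from any specific force field: it
only needs (a) a cheap geometric overlap filter applied before any
energy call, and (b) an object with ``full(chain)`` and
``delta(chain, undo)`` methods returning energies in consistent units
(the Metropolis criterion uses only differences over kT).

The clash filter rejects a conformation when any non-bonded pair is
closer than ``scale_factor`` (default 0.7) times its van der Waals
equilibrium distance, taken as the sum of per-element radii from an
editable table.  Pairs separated by one or two bonds (1-2, 1-3) are
excluded; 1-4 pairs are included by default but configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .chain import BackboneChain
from .geometry import wrap_angle

__all__ = [
    "ClashParams",
    "load_vdw_radii",
    "ExclusionTable",
    "clash_check",
    "DefaultEnergy",
    "TorsionPotential",
]


def load_vdw_radii(path=None) -> dict[str, float]:
    """Element -> vdW equilibrium radius (A); pair distance = sum."""
    if path is None:
        path = resources.files("tripmove.data").joinpath("vdw_radii.txt")
        fh = path.open()
    else:
        fh = open(path)
    radii = {}
    with fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            el, r = line.split()
            radii[el] = float(r)
    return radii


@dataclass
class ClashParams:
    """Settings of the geometric overlap filter."""

    scale_factor: float = 0.7
    radii: dict[str, float] = field(default_factory=load_vdw_radii)
    exclude_14: bool = False  # 1-4 pairs participate in the filter by default

    def __post_init__(self):
        if not 0.0 < self.scale_factor < 1.0:
            raise ValueError("scale_factor must be in (0, 1)")


class ExclusionTable:
    """Bonded-neighbour exclusions (1-2, 1-3 and optionally 1-4)."""

    def __init__(self, chain: BackboneChain, exclude_14: bool = False):
        n = chain.n_atoms
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in chain.bonded_pairs():
            adj[i].add(j)
            adj[j].add(i)
        excluded: list[set[int]] = [set() for _ in range(n)]
        for i in range(n):
            for j in adj[i]:
                excluded[i].add(j)
                for k in adj[j]:
                    if k != i:
                        excluded[i].add(k)
                        if exclude_14:
                            excluded[i].update(x for x in adj[k] if x != i)
        self.excluded = excluded
        self.n_atoms = n
        self._matrix: np.ndarray | None = None

    def is_excluded(self, i: int, j: int) -> bool:
        return j in self.excluded[i]

    @property
    def matrix(self) -> np.ndarray:
        """Dense boolean exclusion matrix (diagonal counts as excluded)."""
        if self._matrix is None:
            m = np.eye(self.n_atoms, dtype=bool)
            for i, ex in enumerate(self.excluded):
                m[i, list(ex)] = True
            self._matrix = m
        return self._matrix

    def pair_mask(self, i: int) -> np.ndarray:
        """Boolean mask over all atoms: True where pair (i, j) is excluded."""
        return self.matrix[i]


def _pair_radii(chain: BackboneChain, params: ClashParams) -> np.ndarray:
    try:
        return np.array([params.radii[e] for e in chain.atom_elements])
    except KeyError as exc:
        raise KeyError(f"no van der Waals radius for element {exc.args[0]!r}") from exc


def clash_check(
    chain: BackboneChain,
    params: ClashParams,
    changed_atoms=None,
    exclusions: ExclusionTable | None = None,
    use_grid: bool = True,
):
    """Overlap test of changed atoms against the whole chain.

    Returns ``(passed, offending_pair)``.  Fails iff some non-excluded
    pair involving a changed atom is strictly closer than
    ``scale_factor`` times its vdW equilibrium distance.  The
    grid-accelerated path and the brute-force path give identical
    verdicts; the grid only prunes pairs beyond the largest cutoff.
    """
    chain.refresh()
    coords = chain.coords
    radii = _pair_radii(chain, params)
    if exclusions is None:
        exclusions = ExclusionTable(chain, params.exclude_14)
    changed = np.arange(chain.n_atoms) if changed_atoms is None else np.asarray(changed_atoms)
    max_cut = params.scale_factor * 2.0 * radii.max()

    if use_grid:
        tree = cKDTree(coords)
        neighbor_lists = tree.query_ball_point(coords[changed], max_cut)
        for i, neigh in zip(changed, neighbor_lists):
            if not neigh:
                continue
            js = np.asarray(neigh)
            js = js[js != i]
            if len(js) == 0:
                continue
            dist = np.linalg.norm(coords[js] - coords[i], axis=1)
            cut = params.scale_factor * (radii[i] + radii[js])
            bad = dist < cut
            if np.any(bad):
                for j in js[bad]:
                    if not exclusions.is_excluded(i, int(j)):
                        return False, (int(min(i, j)), int(max(i, j)))
        return True, None

    # brute force: changed vs all, vectorized
    diff = coords[changed][:, None, :] - coords[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    cut = params.scale_factor * (radii[changed][:, None] + radii[None, :])
    bad = (d < cut) & ~exclusions.matrix[changed]
    if bad.any():
        a, b = np.argwhere(bad)[0]
        i, j = int(changed[a]), int(b)
        return False, (min(i, j), max(i, j))
    return True, None


class DefaultEnergy:
    """Simple deterministic potential driving the Metropolis criterion.

    Nonbonded term: a 12-6 Lennard-Jones form over all non-excluded
    pairs, ``eps_ij [ (r_eq/r)^12 - 2 (r_eq/r)^6 ]`` with its minimum
    ``-eps_ij`` exactly at the pair equilibrium distance
    ``r_eq = R_i + R_j`` (same table as the clash filter).  Pair well
    depths are geometric means of per-element values (kcal/mol).

    Torsional term: ``k_t * (1 + cos(3 theta))`` per variable backbone
    and side-chain torsion, a generic 3-fold hindered-rotation profile.

    ``full`` recomputes from scratch; ``delta`` evaluates only pairs
    and torsions touched by a move (they agree to high precision, which
    the tests assert).
    """

    EPS = {"C": 0.086, "N": 0.170, "O": 0.210, "S": 0.250, "H": 0.016}

    def __init__(self, chain: BackboneChain, params: ClashParams | None = None,
                 k_torsion: float = 0.2, exclude_14: bool = False):
        self.params = params or ClashParams()
        self.radii = _pair_radii(chain, self.params)
        self.eps = np.array([self.EPS[e] for e in chain.atom_elements])
        self.exclusions = ExclusionTable(chain, exclude_14)
        self.k_torsion = k_torsion
        n = chain.n_atoms
        mask = np.ones((n, n), dtype=bool)
        for i in range(n):
            mask[i, list(self.exclusions.excluded[i])] = False
            mask[i, i] = False
        self._mask = mask
        self._triu = np.triu_indices(n, 1)
        # move spans repeat during a run: cache the pair tables per span
        self._span_cache: dict = {}

    # -- nonbonded ------------------------------------------------------

    def _pair_energy(self, r: np.ndarray, eps: np.ndarray, req: np.ndarray) -> np.ndarray:
        x = (req / r) ** 6
        return eps * (x * x - 2.0 * x)

    def nonbonded(self, coords: np.ndarray) -> float:
        i, j = self._triu
        keep = self._mask[i, j]
        i, j = i[keep], j[keep]
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        eps = np.sqrt(self.eps[i] * self.eps[j])
        req = self.radii[i] + self.radii[j]
        return float(self._pair_energy(r, eps, req).sum())

    def torsional(self, chain: BackboneChain) -> float:
        total = 0.0
        tv = chain.torsion_vector()
        total += np.sum(1.0 + np.cos(3.0 * tv))
        for i in range(chain.n_residues):
            c = chain.chi(i)
            if len(c):
                total += np.sum(1.0 + np.cos(3.0 * c))
        return float(self.k_torsion * total)

    def full(self, chain: BackboneChain) -> float:
        chain.refresh()
        return self.nonbonded(chain.coords) + self.torsional(chain)

    def delta(self, chain: BackboneChain, undo: dict) -> float:
        """Energy change of an applied move, given its undo record."""
        chain.refresh()
        changed = undo["atom_sel"]
        old_changed = undo["coords"]
        new = chain.coords
        d = 0.0
        key = (int(changed[0]), int(changed[-1]), len(changed)) if len(changed) else None
        cache = self._span_cache.get(key)
        if cache is None:
            unchanged_mask = np.ones(chain.n_atoms, dtype=bool)
            unchanged_mask[changed] = False
            un = np.where(unchanged_mask)[0]
            eps_x = np.sqrt(np.outer(self.eps[changed], self.eps[un]))
            req_x = self.radii[changed][:, None] + self.radii[un][None, :]
            mask_x = self._mask[np.ix_(changed, un)]
            ii, jj = np.triu_indices(len(changed), 1)
            mask_i = self._mask[changed[ii], changed[jj]]
            eps_i = np.sqrt(self.eps[changed[ii]] * self.eps[changed[jj]])
            req_i = self.radii[changed[ii]] + self.radii[changed[jj]]
            cache = (un, eps_x, req_x, mask_x, ii, jj, mask_i, eps_i, req_i)
            if key is not None:
                self._span_cache[key] = cache
        un, eps_x, req_x, mask_x, ii, jj, mask_i, eps_i, req_i = cache
        # pairs between changed and unchanged atoms
        if len(un) and len(changed):
            diff_n = new[changed][:, None, :] - new[un][None, :, :]
            diff_o = old_changed[:, None, :] - new[un][None, :, :]
            r_new = np.sqrt(np.sum(diff_n * diff_n, axis=2))
            r_old = np.sqrt(np.sum(diff_o * diff_o, axis=2))
            e_new = self._pair_energy(np.where(mask_x, r_new, 1.0), eps_x, req_x)
            e_old = self._pair_energy(np.where(mask_x, r_old, 1.0), eps_x, req_x)
            d += float(np.sum(np.where(mask_x, e_new - e_old, 0.0)))
        # pairs inside the changed set
        if len(changed) > 1:
            r_new = np.linalg.norm(new[changed[ii]] - new[changed[jj]], axis=1)
            r_old = np.linalg.norm(old_changed[ii] - old_changed[jj], axis=1)
            d += float(np.sum(np.where(mask_i, self._pair_energy(r_new, eps_i, req_i)
                                       - self._pair_energy(r_old, eps_i, req_i), 0.0)))
        # torsional changes
        tv_new = chain.torsion_vector()
        tv_old = np.empty_like(tv_new)
        tv_old[0::2] = undo["phi"]
        tv_old[1::2] = undo["psi"]
        d += self.k_torsion * float(np.sum(np.cos(3 * tv_new) - np.cos(3 * tv_old)))
        for i in range(chain.n_residues):
            c_new = chain.chi(i)
            if len(c_new):
                c_old = undo["chi"][i]
                d += self.k_torsion * float(np.sum(np.cos(3 * c_new) - np.cos(3 * c_old)))
        return d


class TorsionPotential:
    """Energy depending on backbone torsions only, ``sum_k f_k(torsion_k)``.

    ``terms`` maps torsion keys ``("phi", i)`` / ``("psi", i)`` to
    callables.  Used for analytically integrable benchmark systems
    (e.g. the two-torsion double well): the Boltzmann marginal of each
    torsion can be computed by direct numerical quadrature.
    """

    def __init__(self, terms: dict):
        self.terms = dict(terms)

    def _value(self, chain: BackboneChain, phi: np.ndarray, psi: np.ndarray) -> float:
        total = 0.0
        for (kind, i), f in self.terms.items():
            total += f(phi[i] if kind == "phi" else psi[i])
        return float(total)

    def full(self, chain: BackboneChain) -> float:
        return self._value(chain, chain.phi, chain.psi)

    def delta(self, chain: BackboneChain, undo: dict) -> float:
        return self._value(chain, chain.phi, chain.psi) - self._value(
            chain, undo["phi"], undo["psi"]
        )
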