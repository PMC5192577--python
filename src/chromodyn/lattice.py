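"""Self-avoiding lattice Monte Carlo of chromatin fibers.

Chains are beads on a cubic lattice with grid constant ``a = 30 nm``;
consecutive beads occupy one of the 26 surrounding sites, giving a mean
bond length of sqrt(2) a ~ 42 nm, one bond corresponding to 2500 bp.
Double occupancy of sites is suppressed (self-avoidance).  Fibers are
built from the domain grammar (linear stretches, rosette domains of
loops, globular domains) and equilibrated with single-bead displacement
moves under hard topological constraints: every loop stays closed (first
and last bead remain lattice neighbors) and consecutive loop bases of a
rosette stay mutually adjacent, forming the rosette center.  The move set
uses symmetric proposals and accepts any constraint-satisfying move, so
the stationary distribution is uniform over valid conformations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .domains import Dom, DomainConfig, Glob, Lin, Loop, parse_domain_config

__all__ = [
    "LatticeSpec",
    "LatticeChain",
    "Ensemble",
    "ChainStatistics",
    "build_initial_chain",
    "mc_equilibrate",
    "sample_ensemble",
    "chain_statistics",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice geometry and genomic calibration."""

    a: float = 30.0  # grid constant [nm]
    bp_per_bond: int = 2500

    def __post_init__(self) -> None:
        if self.a <= 0 or self.bp_per_bond <= 0:
            raise ValueError("lattice constants must be positive")

    @property
    def b(self) -> float:
        """Nominal mean bond length [nm]."""
        return math.sqrt(2.0) * self.a

    def beads(self, kb: float) -> int:
        """Number of beads representing ``kb`` kilobases."""
        n = round(kb * 1000.0 / self.bp_per_bond)
        if n < 1:
            raise ValueError(f"{kb} kb is below one lattice bond")
        return int(n)


# The 26 neighbor displacement vectors, fixed order for reproducibility.
_DIRS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass
class LatticeChain:
    """A conformation plus its topological annotation.

    sites : (N, 3) integer lattice coordinates
    element_id : per-bead index into ``element_tags``
    loops : list of (first_bead, last_bead) index pairs (closed loops)
    base_pairs : extra adjacency constraints between consecutive loop bases
    confinement : optional per-bead (center(3), radius^2) in lattice units
        for globular stretches
    """

    spec: LatticeSpec
    sites: np.ndarray
    element_id: np.ndarray
    element_tags: list[str]
    loops: list[tuple[int, int]] = field(default_factory=list)
    base_pairs: list[tuple[int, int]] = field(default_factory=list)
    confine_center: np.ndarray | None = None
    confine_r2: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return int(self.sites.shape[0])

    @property
    def loop_base_beads(self) -> list[int]:
        return [first for first, _ in self.loops]

    def constraint_pairs(self) -> np.ndarray:
        """All bead index pairs required to be lattice neighbors."""
        n = self.n_beads
        pairs = [(i, i + 1) for i in range(n - 1)]
        pairs += list(self.loops)
        pairs += list(self.base_pairs)
        return np.asarray(pairs, dtype=np.int64)

    def positions_nm(self) -> np.ndarray:
        return self.sites.astype(float) * self.spec.a

    def copy(self) -> "LatticeChain":
        return LatticeChain(
            spec=self.spec,
            sites=self.sites.copy(),
            element_id=self.element_id.copy(),
            element_tags=list(self.element_tags),
            loops=list(self.loops),
            base_pairs=list(self.base_pairs),
            confine_center=None if self.confine_center is None else self.confine_center.copy(),
            confine_r2=None if self.confine_r2 is None else self.confine_r2.copy(),
        )

    def validate(self, self_avoiding: bool = True) -> None:
        """Raise if any chain invariant is violated."""
        if self_avoiding:
            unique = {tuple(s) for s in self.sites}
            if len(unique) != self.n_beads:
                raise ValueError("double occupancy detected")
        for i, j in self.constraint_pairs():
            d = np.abs(self.sites[i] - self.sites[j]).max()
            if d != 1:
                raise ValueError(f"beads {i},{j} are not lattice neighbors (cheb {d})")


def _adjacency_lists(chain: LatticeChain) -> tuple[np.ndarray, np.ndarray]:
    """Flattened per-bead partner lists for the move kernel."""
    partners: list[list[int]] = [[] for _ in range(chain.n_beads)]
    for i, j in chain.constraint_pairs():
        partners[int(i)].append(int(j))
        partners[int(j)].append(int(i))
    starts = np.zeros(chain.n_beads + 1, dtype=np.int64)
    for i, pl in enumerate(partners):
        starts[i + 1] = starts[i] + len(pl)
    flat = np.empty(starts[-1], dtype=np.int64)
    for i, pl in enumerate(partners):
        flat[starts[i] : starts[i + 1]] = pl
    return starts, flat


def _hairpin_loop(base: np.ndarray, n: int, d: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Closed loop of n beads starting at ``base``: out along d, back along -d.

    The last bead lands a single lattice step from the base.
    """
    if n < 4:
        raise ValueError("loops need at least 4 beads to close on the lattice")
    out = []
    if n % 2 == 0:
        m = n // 2 - 1  # out m steps, one side step, back m steps
        for i in range(m + 1):
            out.append(base + i * d)
        for i in range(m, 0, -1):
            out.append(base + i * d + s)
        out.append(base + s)
    else:
        m = (n - 1) // 2
        for i in range(m + 1):
            out.append(base + i * d)
        for i in range(m, 1, -1):
            out.append(base + i * d + s)
        out.append(base + d + s)
    arr = np.array(out, dtype=np.int64)
    assert arr.shape[0] == n
    return arr


def _serpentine(start: np.ndarray, n: int) -> np.ndarray:
    """Compact self-avoiding serpentine block, starting at ``start``.

    Fills y-z planes of side ~ n^(1/3) while advancing along +x, so the
    last bead always sits on the outermost x-plane and the chain can
    continue in +x without collisions.
    """
    side = max(2, math.ceil(n ** (1.0 / 3.0)))
    pts = []
    count = 0
    for ix in range(n // (side * side) + 2):
        for iy_raw in range(side):
            iy = iy_raw if ix % 2 == 0 else side - 1 - iy_raw
            row = ix * side + iy_raw  # global traversal row index
            for iz_raw in range(side):
                iz = iz_raw if row % 2 == 0 else side - 1 - iz_raw
                pts.append((ix, iy, iz))
                count += 1
                if count == n:
                    return start + np.array(pts, dtype=np.int64)
    raise RuntimeError("serpentine construction failed")  # pragma: no cover


def build_initial_chain(
    config: DomainConfig | str,
    lattice: LatticeSpec | None = None,
    seed: int | None = None,
    variant_index: int | None = None,
    glob_volume_fraction: float = 0.1,
) -> LatticeChain:
    """Deterministically place a configuration on the lattice.

    Elements are laid out along +x: linear stretches as straight runs,
    rosette loops as hairpins in the y-z plane of their base (bases on
    consecutive x sites, hence mutually adjacent), globs as compact
    serpentine blocks.  The construction is collision-free by design; the
    ``seed`` only matters for downstream equilibration and is recorded for
    provenance.  Varied loop lengths are resolved with ``variant_index``
    (None = mean length).
    """
    if isinstance(config, str):
        config = parse_domain_config(config)
    lattice = lattice or LatticeSpec()
    sites: list[np.ndarray] = []
    element_id: list[int] = []
    element_tags: list[str] = []
    loops: list[tuple[int, int]] = []
    base_pairs: list[tuple[int, int]] = []
    confine: list[tuple[int, int, np.ndarray, float]] = []  # (i0, i1, center, r2)

    xhat = np.array([1, 0, 0], dtype=np.int64)
    cursor = np.zeros(3, dtype=np.int64)  # next bead position

    def extend(new_sites: np.ndarray, tag: str) -> tuple[int, int]:
        i0 = len(sites)
        eid = len(element_tags)
        element_tags.append(tag)
        for p in new_sites:
            sites.append(np.asarray(p, dtype=np.int64))
            element_id.append(eid)
        return i0, len(sites) - 1

    hairpin_axes = [
        (np.array([0, 1, 0], np.int64), np.array([0, 0, 1], np.int64)),
        (np.array([0, -1, 0], np.int64), np.array([0, 0, 1], np.int64)),
        (np.array([0, 0, 1], np.int64), np.array([0, 1, 0], np.int64)),
        (np.array([0, 0, -1], np.int64), np.array([0, 1, 0], np.int64)),
    ]

    for el_idx, element in enumerate(config.elements):
        if isinstance(element, Lin):
            n = lattice.beads(element.kb)
            pts = np.array([cursor + i * xhat for i in range(n)])
            extend(pts, f"lin{el_idx}")
            cursor = pts[-1] + xhat
        elif isinstance(element, Dom):
            if element.is_rosette:
                prev_base_last = None
                for li, loop in enumerate(element.content):
                    assert isinstance(loop, Loop)
                    n = lattice.beads(loop.length(variant_index))
                    d, s = hairpin_axes[li % len(hairpin_axes)]
                    base = cursor.copy()
                    pts = _hairpin_loop(base, n, d, s)
                    i0, i1 = extend(pts, f"dom{el_idx}.loop{li}")
                    loops.append((i0, i1))
                    if prev_base_last is not None:
                        base_pairs.append((prev_base_last, i0))
                    prev_base_last = i0
                    cursor = base + xhat
            else:
                glob = element.content[0]
                assert isinstance(glob, Glob)
                n = lattice.beads(glob.kb)
                pts = _serpentine(cursor.copy(), n)
                i0, i1 = extend(pts, f"dom{el_idx}.glob")
                center = pts.mean(axis=0)
                # confining sphere sized for target volume fraction phi
                r = (3.0 * n / (4.0 * math.pi * glob_volume_fraction)) ** (1.0 / 3.0)
                confine.append((i0, i1, center, r * r))
                cursor = pts[-1] + xhat  # last bead is on the outermost x-plane
        else:  # pragma: no cover
            raise TypeError(f"unsupported element {element!r}")

    arr = np.array(sites, dtype=np.int64)
    chain = LatticeChain(
        spec=lattice,
        sites=arr,
        element_id=np.array(element_id, dtype=np.int64),
        element_tags=element_tags,
        loops=loops,
        base_pairs=base_pairs,
    )
    if confine:
        center = np.zeros((chain.n_beads, 3), dtype=np.float64)
        r2 = np.full(chain.n_beads, np.inf)
        for i0, i1, c, rr in confine:
            center[i0 : i1 + 1] = c
            r2[i0 : i1 + 1] = rr
        chain.confine_center = center
        chain.confine_r2 = r2
    chain.validate()
    return chain


@njit(cache=False)
def _run_moves(
    pos,
    occ,
    origin,
    shape,
    part_starts,
    part_flat,
    confine_center,
    confine_r2,
    dirs,
    bead_choice,
    dir_choice,
    self_avoiding,
):  # pragma: no cover - exercised via mc_equilibrate
    n_acc = 0
    n_att = bead_choice.shape[0]
    for k in range(n_att):
        i = bead_choice[k]
        d = dirs[dir_choice[k]]
        qx = pos[i, 0] + d[0]
        qy = pos[i, 1] + d[1]
        qz = pos[i, 2] + d[2]
        gx = qx - origin[0]
        gy = qy - origin[1]
        gz = qz - origin[2]
        if gx < 0 or gy < 0 or gz < 0 or gx >= shape[0] or gy >= shape[1] or gz >= shape[2]:
            continue
        if self_avoiding and occ[gx, gy, gz] != 0:
            continue
        if confine_r2[i] != np.inf:
            dx = qx - confine_center[i, 0]
            dy = qy - confine_center[i, 1]
            dz = qz - confine_center[i, 2]
            if dx * dx + dy * dy + dz * dz > confine_r2[i]:
                continue
        ok = True
        for pidx in range(part_starts[i], part_starts[i + 1]):
            j = part_flat[pidx]
            ax = qx - pos[j, 0]
            if ax < 0:
                ax = -ax
            ay = qy - pos[j, 1]
            if ay < 0:
                ay = -ay
            az = qz - pos[j, 2]
            if az < 0:
                az = -az
            cheb = ax
            if ay > cheb:
                cheb = ay
            if az > cheb:
                cheb = az
            if cheb != 1:
                ok = False
                break
        if not ok:
            continue
        if self_avoiding:
            occ[pos[i, 0] - origin[0], pos[i, 1] - origin[1], pos[i, 2] - origin[2]] = 0
            occ[gx, gy, gz] = 1
        pos[i, 0] = qx
        pos[i, 1] = qy
        pos[i, 2] = qz
        n_acc += 1
    return n_acc


class _MCState:
    """Occupancy grid + adjacency tables reused across sweeps."""

    def __init__(self, chain: LatticeChain, margin: int = 120, self_avoiding: bool = True):
        self.chain = chain
        self.self_avoiding = self_avoiding
        lo = chain.sites.min(axis=0) - margin
        hi = chain.sites.max(axis=0) + margin
        self.origin = lo.astype(np.int64)
        self.shape = (hi - lo + 1).astype(np.int64)
        self.occ = np.zeros(tuple(self.shape), dtype=np.uint8)
        rel = chain.sites - self.origin
        if self_avoiding:
            self.occ[rel[:, 0], rel[:, 1], rel[:, 2]] = 1
        self.part_starts, self.part_flat = _adjacency_lists(chain)
        if chain.confine_center is None:
            self.confine_center = np.zeros((chain.n_beads, 3), dtype=np.float64)
            self.confine_r2 = np.full(chain.n_beads, np.inf)
        else:
            self.confine_center = chain.confine_center
            self.confine_r2 = chain.confine_r2

    def run(self, rng: np.random.Generator, n_attempts: int) -> int:
        bead = rng.integers(0, self.chain.n_beads, size=n_attempts).astype(np.int64)
        dirc = rng.integers(0, 26, size=n_attempts).astype(np.int64)
        return int(
            _run_moves(
                self.chain.sites,
                self.occ,
                self.origin,
                self.shape,
                self.part_starts,
                self.part_flat,
                self.confine_center,
                self.confine_r2,
                _DIRS,
                bead,
                dirc,
                self.self_avoiding,
            )
        )


def mc_equilibrate(
    chain: LatticeChain,
    n_sweeps: int,
    seed: int | np.random.Generator,
    self_avoiding: bool = True,
    margin: int = 120,
) -> tuple[LatticeChain, float]:
    """Equilibrate in place for ``n_sweeps`` (one attempted move per bead
    per sweep); returns the chain and the move acceptance ratio."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = _MCState(chain, margin=margin, self_avoiding=self_avoiding)
    attempts = n_sweeps * chain.n_beads
    accepted = 0
    chunk = 2_000_000
    done = 0
    while done < attempts:
        m = min(chunk, attempts - done)
        accepted += state.run(rng, m)
        done += m
    return chain, accepted / max(attempts, 1)


def random_walk_chain(
    n_beads: int, lattice: LatticeSpec | None = None, seed: int = 0
) -> LatticeChain:
    """Phantom linear chain with independent uniform bonds.

    Uniform random bond vectors over the 26 neighbor displacements are the
    exact equilibrium distribution of the unconstrained (phantom) linear
    chain, so this is an equilibrium sample by construction.  Collisions
    are allowed; use only with ``self_avoiding=False``.
    """
    lattice = lattice or LatticeSpec()
    rng = np.random.default_rng(seed)
    bonds = _DIRS[rng.integers(0, 26, size=n_beads - 1)]
    sites = np.vstack([np.zeros(3, dtype=np.int64), np.cumsum(bonds, axis=0)])
    return LatticeChain(
        spec=lattice,
        sites=sites,
        element_id=np.zeros(n_beads, dtype=np.int64),
        element_tags=["lin0"],
    )


@dataclass
class Ensemble:
    """Equilibrated conformations of one configuration."""

    chain_template: LatticeChain
    conformations: list[np.ndarray]  # lattice sites per sample
    seed: int
    acceptance: float
    sweeps_burn_in: int
    sweeps_between: int

    @property
    def n(self) -> int:
        return len(self.conformations)

    def positions_nm(self, index: int) -> np.ndarray:
        return self.conformations[index].astype(float) * self.chain_template.spec.a

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["seed"] = self.seed
            fh.attrs["acceptance"] = self.acceptance
            fh.attrs["a_nm"] = self.chain_template.spec.a
            fh.attrs["bp_per_bond"] = self.chain_template.spec.bp_per_bond
            fh.create_dataset("element_id", data=self.chain_template.element_id)
            grp = fh.create_group("conformations")
            for i, sites in enumerate(self.conformations):
                grp.create_dataset(f"conf_{i:05d}", data=sites, compression="gzip")


def sample_ensemble(
    config: DomainConfig | str,
    n_conformations: int,
    seed: int,
    sweeps_burn_in: int | None = None,
    sweeps_between: int | None = None,
    lattice: LatticeSpec | None = None,
    self_avoiding: bool = True,
    variant_cycle: bool = True,
) -> Ensemble:
    """Sample ``n_conformations`` equilibrated conformations.

    A fresh chain is built and burnt in per variant of the configuration
    (loop-length variants are cycled when ``variant_cycle``), then samples
    are taken every ``sweeps_between`` sweeps along the Markov chain.
    Defaults: burn-in 20 sweeps per bead, 4 sweeps per bead between
    samples — generous for the loop sizes used here, where the slowest
    internal relaxation is set by single-loop Rouse times.
    """
    if n_conformations < 1:
        raise ValueError("need n_conformations >= 1")
    if isinstance(config, str):
        config = parse_domain_config(config)
    lattice = lattice or LatticeSpec()
    rng = np.random.default_rng(seed)

    n_variants = 1
    if variant_cycle:
        for dom in config.domains():
            if dom.is_rosette:
                for loop in dom.content:
                    if isinstance(loop, Loop) and loop.variants:
                        n_variants = max(n_variants, len(loop.variants))

    probe = build_initial_chain(config, lattice, variant_index=0 if n_variants > 1 else None)
    burn = sweeps_burn_in if sweeps_burn_in is not None else 20 * probe.n_beads
    between = sweeps_between if sweeps_between is not None else 4 * probe.n_beads

    samples: list[np.ndarray] = []
    acc_total = 0.0
    n_runs = 0
    per_variant = [n_conformations // n_variants] * n_variants
    for i in range(n_conformations % n_variants):
        per_variant[i] += 1
    for vi, n_v in enumerate(per_variant):
        if n_v == 0:
            continue
        chain = build_initial_chain(
            config, lattice, variant_index=vi if n_variants > 1 else None
        )
        _, acc = mc_equilibrate(chain, burn, rng, self_avoiding=self_avoiding)
        acc_total += acc
        n_runs += 1
        samples.append(chain.sites.copy())
        for _ in range(n_v - 1):
            mc_equilibrate(chain, between, rng, self_avoiding=self_avoiding)
            samples.append(chain.sites.copy())
    template = build_initial_chain(config, lattice, variant_index=0 if n_variants > 1 else None)
    return Ensemble(
        chain_template=template,
        conformations=samples,
        seed=seed,
        acceptance=acc_total / max(n_runs, 1),
        sweeps_burn_in=burn,
        sweeps_between=between,
    )


@dataclass(frozen=True)
class ChainStatistics:
    rg_mean: float  # nm
    rg_sd: float
    rg_values: np.ndarray
    bond_hist: dict[float, float]  # bond length [nm] -> frequency
    mean_bond: float
    end_to_end_mean: float


def _rg(positions_nm: np.ndarray) -> float:
    c = positions_nm.mean(axis=0)
    return float(np.sqrt(((positions_nm - c) ** 2).sum(axis=1).mean()))


def chain_statistics(ensemble: Ensemble, bead_slice: slice | None = None) -> ChainStatistics:
    """Gyration radius, bond-length histogram and end-to-end statistics.

    ``bead_slice`` restricts the analysis to part of the chain (e.g. one
    domain).  R_g is the root mean squared distance of beads from the
    centroid.
    """
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    a = ensemble.chain_template.spec.a
    sl = bead_slice if bead_slice is not None else slice(None)
    rgs = []
    e2e = []
    bond_counts: dict[float, int] = {}
    total_bonds = 0
    for sites in ensemble.conformations:
        pos = sites[sl].astype(float) * a
        rgs.append(_rg(pos))
        e2e.append(float(np.linalg.norm(pos[-1] - pos[0])))
        d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        for val in np.round(d, 6):
            bond_counts[val] = bond_counts.get(val, 0) + 1
            total_bonds += 1
    rgs = np.asarray(rgs)
    mean_bond = sum(k * v for k, v in bond_counts.items()) / total_bonds
    return ChainStatistics(
        rg_mean=float(rgs.mean()),
        rg_sd=float(rgs.std(ddof=1)) if rgs.size > 1 else 0.0,
        rg_values=rgs,
        bond_hist={k: v / total_bonds for k, v in sorted(bond_counts.items())},
        mean_bond=float(mean_bond),
        end_to_end_mean=float(np.mean(e2e)),
    )
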