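"""Multiscale beads-on-a-string Monte Carlo chromatin modeling.

Three stages, each fitting bead coordinates to distance restraints by
simulated annealing with a final deterministic quench:

* low resolution -- one bead per (megabase-scale, unequal) bin of a
  singleton contact heatmap; target distances follow the inverse power
  law ``d_ij = c * f_ij**(-alpha)`` and the energy is the sum of squared
  residuals ``(d_ij - r_ij)**2`` over pairs with observed contacts.
* anchor stage -- one bead per loop anchor inside a block (connected
  component of the anchor-loop graph); loop-connected pairs get targets
  from the exponential law ``d_ij = delta + a * exp(-upsilon*(f_ij -
  gamma))``; unconnected pairs contribute no term.
* subloop stage -- ``k`` subanchor beads per loop between consecutive
  anchors; anchors stay fixed while subanchors relax under a stretching
  term ``E_s = sum (r_{i,i+1} - (N_{i,i+1}/g0)**beta)**2``, a bending term
  ``E_b = 0.5 * sum (1 - u_{i-1,i} . u_{i,i+1})**2`` and an optional
  heatmap term ``E_h`` of squared residuals against expected distances
  modulated by singleton frequencies.

All energies are functions of inter-bead geometry only, hence invariant
under rigid motions. Annealing runs accept a move when its energy change
is negative, or with Boltzmann probability otherwise; the best-seen
configuration is kept, so final energy never exceeds the initial one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .core import Network


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing schedule (geometric cooling)."""

    initial_temperature: float = 1.0
    cooling: float = 0.995
    n_sweeps: int = 300
    step_size: float = 0.5
    target_acceptance: float = 0.4
    polish: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass(frozen=True)
class EnergyParams:
    """Distance-law and chain parameters for all three stages.

    None of these is dictated by the data model itself; defaults are
    package choices, documented in docs/methods.md, and every acceptance
    property of the engine is robust to them.
    """

    alpha_low: float = 1.0      # low-res power-law exponent
    scale_c: float = 1.0        # low-res power-law scale
    delta: float = 0.5          # anchor law floor distance
    a: float = 3.0              # anchor law amplitude
    upsilon: float = 0.3        # anchor law decay rate (> 0)
    gamma: float = 1.0          # anchor law frequency offset
    beta: float = 0.6           # stretch exponent on genomic distance
    genomic_unit: float = 1000.0  # bp per spatial-target unit in E_s
    k_subanchors: int = 3       # subanchor beads per loop
    heatmap_modulation: float = 0.5
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)

    def __post_init__(self) -> None:
        if self.upsilon <= 0:
            raise ValueError("upsilon must be > 0")
        if self.k_subanchors < 1:
            raise ValueError("k_subanchors must be >= 1")

    def anchor_target(self, frequency: float) -> float:
        return self.delta + self.a * math.exp(-self.upsilon * (frequency - self.gamma))

    def lowres_target(self, frequency: float) -> float:
        return self.scale_c * frequency ** (-self.alpha_low)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """An ordered bead chain with genomic spans and 3D coordinates."""

    beads: list[tuple[str, int, int]]
    coords: np.ndarray
    level: str = "anchor"
    energies: dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def bead_centers(self) -> np.ndarray:
        return np.array([(s + e) / 2.0 for _, s, e in self.beads])

    def locate(self, chrom: str, pos: int) -> int:
        """Bead index whose span contains ``pos`` (nearest bead if none)."""
        idx = [i for i, (c, s, e) in enumerate(self.beads)
               if c == chrom and s <= pos < e]
        if idx:
            centers = self.bead_centers()
            return min(idx, key=lambda i: (abs(centers[i] - pos), i))
        on_chrom = [i for i, (c, _s, _e) in enumerate(self.beads) if c == chrom]
        if not on_chrom:
            raise ValueError(f"locus {chrom}:{pos} outside modeled region")
        lo = min(self.beads[i][1] for i in on_chrom)
        hi = max(self.beads[i][2] for i in on_chrom)
        if not (lo <= pos < hi):
            raise ValueError(f"locus {chrom}:{pos} outside modeled region "
                             f"[{lo}, {hi})")
        centers = self.bead_centers()
        return min(on_chrom, key=lambda i: (abs(centers[i] - pos), i))

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))


@dataclass
class Ensemble:
    structures: list[Structure]
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return len(self.structures)


@dataclass
class SingletonHeatmap:
    """Symmetric contact-frequency matrix over unequal genomic bins."""

    chrom: str
    boundaries: np.ndarray  # length n+1, increasing
    frequencies: np.ndarray  # n x n, symmetric, nonnegative

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValueError("frequency matrix must be square")
        if f.shape[0] != len(b) - 1:
            raise ValueError("boundaries must have n+1 entries")
        if np.any(np.diff(b) <= 0):
            raise ValueError("bin boundaries must be increasing")
        if not np.allclose(f, f.T):
            raise ValueError("frequency matrix must be symmetric")
        if (f < 0).any():
            raise ValueError("frequencies must be nonnegative")
        self.boundaries = b
        self.frequencies = f

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    @classmethod
    def from_contacts(cls, chrom: str, boundaries: Sequence[int],
                      contacts: Sequence[tuple[int, int]]) -> "SingletonHeatmap":
        """Bin a list of (pos_a, pos_b) singleton contacts."""
        b = np.asarray(boundaries)
        n = len(b) - 1
        f = np.zeros((n, n))
        for x, y in contacts:
            i = int(np.searchsorted(b, x, side="right")) - 1
            j = int(np.searchsorted(b, y, side="right")) - 1
            if 0 <= i < n and 0 <= j < n:
                f[i, j] += 1
                if i != j:
                    f[j, i] += 1
        return cls(chrom, b, f)

    def bin_of(self, pos: int) -> int:
        return int(np.searchsorted(self.boundaries, pos, side="right")) - 1


# ---------------------------------------------------------------------------
# Energy models
# ---------------------------------------------------------------------------

class PairEnergy:
    """Sum of squared residuals against target distances for bead pairs."""

    def __init__(self, n_beads: int, pairs: Sequence[tuple[int, int, float]]):
        self.n = n_beads
        self.i = np.array([p[0] for p in pairs], dtype=int)
        self.j = np.array([p[1] for p in pairs], dtype=int)
        self.d = np.array([p[2] for p in pairs], dtype=float)
        self._by_bead: list[np.ndarray] = [
            np.flatnonzero((self.i == b) | (self.j == b)) for b in range(n_beads)
        ]

    def total(self, coords: np.ndarray) -> float:
        if self.i.size == 0:
            return 0.0
        r = np.linalg.norm(coords[self.i] - coords[self.j], axis=1)
        return float(np.sum((self.d - r) ** 2))

    def local(self, coords: np.ndarray, bead: int) -> float:
        terms = self._by_bead[bead]
        if terms.size == 0:
            return 0.0
        r = np.linalg.norm(coords[self.i[terms]] - coords[self.j[terms]], axis=1)
        return float(np.sum((self.d[terms] - r) ** 2))

    def residuals(self, coords: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(coords[self.i] - coords[self.j], axis=1)
        return np.abs(self.d - r)


class ChainEnergy:
    """Stretch + bending + optional pair restraints along one bead chain.

    E_s runs over consecutive beads with targets ``t_k``; E_b over interior
    beads; extra pair targets (the heatmap term E_h) are added via
    ``pair_terms``.
    """

    def __init__(self, n_beads: int, stretch_targets: np.ndarray,
                 bend_weight: float = 1.0,
                 pair_terms: Optional[PairEnergy] = None):
        if len(stretch_targets) != n_beads - 1:
            raise ValueError("need n-1 stretch targets")
        self.n = n_beads
        self.t = np.asarray(stretch_targets, dtype=float)
        self.bend_weight = bend_weight
        self.pairs = pair_terms

    # -- components --------------------------------------------------------
    def stretch(self, coords: np.ndarray) -> float:
        r = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        return float(np.sum((r - self.t) ** 2))

    def bend(self, coords: np.ndarray) -> float:
        d = np.diff(coords, axis=0)
        norms = np.linalg.norm(d, axis=1)
        norms = np.where(norms == 0, 1.0, norms)
        u = d / norms[:, None]
        dots = np.sum(u[:-1] * u[1:], axis=1)
        return float(0.5 * self.bend_weight * np.sum((1.0 - dots) ** 2))

    def heat(self, coords: np.ndarray) -> float:
        return self.pairs.total(coords) if self.pairs is not None else 0.0

    def total(self, coords: np.ndarray) -> float:
        return self.stretch(coords) + self.bend(coords) + self.heat(coords)

    def components(self, coords: np.ndarray) -> dict[str, float]:
        return {"E_s": self.stretch(coords), "E_b": self.bend(coords),
                "E_h": self.heat(coords)}

    def local(self, coords: np.ndarray, bead: int) -> float:
        lo = max(0, bead - 2)
        hi = min(self.n, bead + 3)
        sub = coords[lo:hi]
        r = np.linalg.norm(np.diff(sub, axis=0), axis=1)
        t = self.t[lo:hi - 1]
        e = float(np.sum((r - t) ** 2))
        if len(sub) >= 3:
            norms = np.where(r == 0, 1.0, r)
            u = np.diff(sub, axis=0) / norms[:, None]
            dots = np.sum(u[:-1] * u[1:], axis=1)
            e += float(0.5 * self.bend_weight * np.sum((1.0 - dots) ** 2))
        if self.pairs is not None:
            e += self.pairs.local(coords, bead)
        return e


# ---------------------------------------------------------------------------
# Annealer
# ---------------------------------------------------------------------------

def anneal(
    energy,
    coords0: np.ndarray,
    rng: np.random.Generator,
    schedule: Optional[AnnealSchedule] = None,
    free: Optional[np.ndarray] = None,
    record_trace: bool = False,
) -> tuple[np.ndarray, dict]:
    """Minimize ``energy`` over bead coordinates.

    Metropolis single-bead Gaussian moves with geometric cooling and step
    size adapted toward the target acceptance rate, followed (optionally)
    by a deterministic L-BFGS quench of the best-seen configuration. At
    zero temperature only downhill moves are accepted. Returns
    (coordinates, info) where info holds initial/final energies and, when
    requested, the accepted-move energy trace.
    """
    sched = schedule or AnnealSchedule()
    coords = np.array(coords0, dtype=float)
    n = len(coords)
    free_idx = np.arange(n) if free is None else np.flatnonzero(free)
    e_total = energy.total(coords)
    e_init = e_total
    best = coords.copy()
    best_e = e_total
    trace = [e_total] if record_trace else None
    temp = sched.initial_temperature
    step = sched.step_size
    if free_idx.size:
        for _sweep in range(sched.n_sweeps):
            accepted = 0
            for i in free_idx:
                old = coords[i].copy()
                e_old = energy.local(coords, i)
                coords[i] = old + rng.normal(0.0, step, 3)
                d_e = energy.local(coords, i) - e_old
                if d_e <= 0 or (temp > 0 and rng.random() < math.exp(-d_e / temp)):
                    e_total += d_e
                    accepted += 1
                    if record_trace:
                        trace.append(e_total)
                    if e_total < best_e:
                        best_e = e_total
                        best = coords.copy()
                else:
                    coords[i] = old
            rate = accepted / free_idx.size
            step *= 1.1 if rate > sched.target_acceptance else 0.9
            step = min(max(step, 1e-4), 10.0)
            temp *= sched.cooling
    if sched.polish and free_idx.size:
        best = _quench(energy, best, free_idx)
        best_e = energy.total(best)
        if best_e > e_init:  # defensive; quench of best never goes above init
            best_e = e_init
    info = {"E_initial": e_init, "E_final": min(best_e, e_init)}
    if record_trace:
        info["trace"] = trace
    return best, info


def _quench(energy, coords: np.ndarray, free_idx: np.ndarray) -> np.ndarray:
    base = coords.copy()

    def fun(x: np.ndarray) -> float:
        c = base.copy()
        c[free_idx] = x.reshape(-1, 3)
        return energy.total(c)

    res = optimize.minimize(fun, coords[free_idx].ravel(), method="L-BFGS-B",
                            options={"maxiter": 300, "ftol": 1e-14,
                                     "gtol": 1e-12})
    out = base.copy()
    if res.fun <= energy.total(coords):
        out[free_idx] = res.x.reshape(-1, 3)
    return out


def _random_init(n: int, rng: np.random.Generator, scale: float) -> np.ndarray:
    if n == 1:
        return np.zeros((1, 3))
    return rng.normal(0.0, scale, (n, 3))


# ---------------------------------------------------------------------------
# Stage drivers
# ---------------------------------------------------------------------------

def split_blocks(net: Network, loop_ids: Optional[Sequence[int]] = None
                 ) -> list[list[int]]:
    """Connected components of the anchor-loop graph, anchors sorted."""
    loops = net.loops if loop_ids is None else [net.loops[i] for i in loop_ids]
    adj: dict[int, set[int]] = {}
    for lp in loops:
        adj.setdefault(lp.a, set()).add(lp.b)
        adj.setdefault(lp.b, set()).add(lp.a)
    seen: set[int] = set()
    blocks = []
    for start in sorted(adj, key=lambda i: (net.anchors[i].chrom,
                                            net.anchors[i].start, i)):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comp.sort(key=lambda i: (net.anchors[i].start, i))
        blocks.append(comp)
    blocks.sort(key=lambda b: net.anchors[b[0]].start)
    return blocks


def model_lowres(heatmap: SingletonHeatmap, params: EnergyParams,
                 rng: np.random.Generator) -> Structure:
    """Position one bead per heatmap bin against the inverse power law."""
    n = heatmap.n_bins
    beads = [(heatmap.chrom, int(heatmap.boundaries[i]),
              int(heatmap.boundaries[i + 1])) for i in range(n)]
    if n == 1:
        return Structure(beads, np.zeros((1, 3)), level="chromosome",
                         energies={"E_initial": 0.0, "E_final": 0.0})
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            f = heatmap.frequencies[i, j]
            if f > 0:
                pairs.append((i, j, params.lowres_target(f)))
    energy = PairEnergy(n, pairs)
    scale = float(np.mean([p[2] for p in pairs])) if pairs else 1.0
    coords, info = anneal(energy, _random_init(n, rng, scale), rng,
                          params.anneal)
    return Structure(beads, coords, level="chromosome", energies=info)


def model_anchors(net: Network, block: Sequence[int], params: EnergyParams,
                  rng: np.random.Generator) -> Structure:
    """Position the anchors of one block against the exponential law."""
    if len(block) < 2:
        raise ValueError("block must have >= 2 anchors")
    order = {aid: k for k, aid in enumerate(block)}
    anchors = [net.anchors[aid] for aid in block]
    beads = [(a.chrom, a.start, a.end) for a in anchors]
    pairs = []
    for lp in net.loops:
        if lp.a in order and lp.b in order:
            pairs.append((order[lp.a], order[lp.b],
                          params.anchor_target(lp.frequency)))
    energy = PairEnergy(len(block), pairs)
    scale = params.delta + params.a
    coords, info = anneal(energy, _random_init(len(block), rng, scale), rng,
                          params.anneal)
    return Structure(beads, coords, level="anchor", energies=info)


def model_subloops(net: Network, block: Sequence[int],
                   anchor_structure: Structure, params: EnergyParams,
                   rng: np.random.Generator,
                   heatmap: Optional[SingletonHeatmap] = None) -> Structure:
    """Insert k subanchor beads per loop and relax them, anchors fixed."""
    k = params.k_subanchors
    anchors = [net.anchors[aid] for aid in block]
    chrom = anchors[0].chrom
    centers = [a.midpoint for a in anchors]
    # chain: anchor, k subbeads, anchor, k subbeads, ...
    bead_centers: list[float] = []
    is_anchor: list[bool] = []
    for idx, c in enumerate(centers):
        bead_centers.append(c)
        is_anchor.append(True)
        if idx + 1 < len(centers):
            nxt = centers[idx + 1]
            span = nxt - c
            if span <= 0:
                continue  # degenerate zero-length span: loop skipped
            for s in range(1, k + 1):
                bead_centers.append(c + span * s / (k + 1))
                is_anchor.append(False)
    n = len(bead_centers)
    # bead spans: midpoints between consecutive centers (Voronoi partition)
    edges = [anchors[0].start * 1.0]
    for x, y in zip(bead_centers, bead_centers[1:]):
        edges.append((x + y) / 2.0)
    edges.append(float(anchors[-1].end))
    beads = [(chrom, int(edges[i]), max(int(edges[i + 1]), int(edges[i]) + 1))
             for i in range(n)]

    genomic = np.diff(np.array(bead_centers))
    stretch_targets = (np.maximum(genomic, 1.0) / params.genomic_unit) ** params.beta

    coords0 = np.zeros((n, 3))
    a_pos = 0
    anchor_idx = []
    for i, flag in enumerate(is_anchor):
        if flag:
            coords0[i] = anchor_structure.coords[a_pos]
            anchor_idx.append(i)
            a_pos += 1
    # seed subbeads on noisy linear interpolation between their anchors
    for left, right in zip(anchor_idx, anchor_idx[1:]):
        for j in range(left + 1, right):
            t = (j - left) / (right - left)
            coords0[j] = (1 - t) * coords0[left] + t * coords0[right]
            coords0[j] += rng.normal(0.0, 0.25, 3)
    free = ~np.array(is_anchor)

    chain = ChainEnergy(n, stretch_targets)
    if heatmap is not None:
        # expected distances under physical constraints only: a pre-relaxation
        pre_sched = replace(params.anneal, n_sweeps=max(params.anneal.n_sweeps // 4, 50))
        pre_coords, _ = anneal(chain, coords0, rng, pre_sched, free=free)
        fmax = heatmap.frequencies.max()
        pairs = []
        if fmax > 0:
            for i in range(n):
                for j in range(i + 1, n):
                    bi = heatmap.bin_of(int(bead_centers[i]))
                    bj = heatmap.bin_of(int(bead_centers[j]))
                    if bi < 0 or bj < 0 or bi >= heatmap.n_bins or bj >= heatmap.n_bins:
                        continue
                    f = heatmap.frequencies[bi, bj]
                    if f <= 0 or bi == bj:
                        continue
                    d_exp = float(np.linalg.norm(pre_coords[i] - pre_coords[j]))
                    w = f / fmax
                    target = d_exp * (1.0 + params.heatmap_modulation * (0.5 - w))
                    pairs.append((i, j, target))
        chain = ChainEnergy(n, stretch_targets,
                            pair_terms=PairEnergy(n, pairs) if pairs else None)
        coords0 = pre_coords

    coords, info = anneal(chain, coords0, rng, params.anneal, free=free)
    energies = dict(info)
    energies.update(chain.components(coords))
    energies["E"] = chain.total(coords)
    return Structure(beads, coords, level="subloop", energies=energies)


def model_blocks(net: Network, params: EnergyParams,
                 rng: np.random.Generator,
                 with_subloops: bool = True,
                 heatmap: Optional[SingletonHeatmap] = None) -> Structure:
    """Model every block of a (single-chromosome) network as one chain.

    Blocks are modeled independently and laid out left to right, separated
    by the stretch-law distance of the genomic gap between them. Lone
    anchors (no loops) are skipped.
    """
    blocks = [b for b in split_blocks(net) if len(b) >= 2]
    if not blocks:
        raise ValueError("network has no block with >= 2 anchors")
    parts: list[Structure] = []
    for block in blocks:
        st = model_anchors(net, block, params, rng)
        if with_subloops:
            st = model_subloops(net, block, st, params, rng, heatmap=heatmap)
        parts.append(st)
    if len(parts) == 1:
        return parts[0]
    beads: list[tuple[str, int, int]] = []
    coords_list = []
    offset = np.zeros(3)
    prev_end = None
    for st, block in zip(parts, blocks):
        c = st.coords - st.coords.mean(axis=0)
        extent = float(np.abs(c[:, 0]).max()) if len(c) > 1 else 1.0
        if prev_end is not None:
            gap_bp = max(net.anchors[block[0]].start - prev_end, 1)
            gap_d = (gap_bp / params.genomic_unit) ** params.beta
            offset[0] += extent + gap_d
        beads.extend(st.beads)
        coords_list.append(c + offset)
        offset[0] += extent
        prev_end = net.anchors[block[-1]].end
    energies = {"E_initial": sum(p.energies.get("E_initial", 0.0) for p in parts),
                "E_final": sum(p.energies.get("E_final", 0.0) for p in parts)}
    return Structure(beads, np.vstack(coords_list),
                     level=parts[0].level, energies=energies)


def generate_ensemble(build: Callable[[np.random.Generator], Structure],
                      n: int, seed: int) -> Ensemble:
    """n independent models from seeds seed, seed+1, ...; reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    structures = []
    for i in range(n):
        st = build(np.random.default_rng(seed + i))
        st.seed = seed + i
        structures.append(st)
    return Ensemble(structures=structures, seed=seed)


def ensemble_for_network(net: Network, params: EnergyParams, n: int,
                         seed: int, with_subloops: bool = True,
                         heatmap: Optional[SingletonHeatmap] = None) -> Ensemble:
    return generate_ensemble(
        lambda rng: model_blocks(net, params, rng, with_subloops=with_subloops,
                                 heatmap=heatmap),
        n, seed,
    )


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------

@dataclass
class DistanceComparison:
    name: str
    ref_distances: np.ndarray
    alt_distances: np.ndarray
    ref_median: float
    alt_median: float
    ref_iqr: float
    alt_iqr: float
    p_value: float


def _pair_distances(ens: Ensemble, loci: Sequence[tuple[str, int]]) -> np.ndarray:
    out = np.empty(ens.n)
    for s_idx, st in enumerate(ens.structures):
        beads = [st.locate(c, p) for c, p in loci]
        if len(beads) == 2:
            out[s_idx] = st.distance(beads[0], beads[1])
        else:  # anchor locus vs mean over the rest (enhancer aggregation)
            ref = beads[0]
            out[s_idx] = float(np.mean([st.distance(ref, b) for b in beads[1:]]))
    return out


def ensemble_distance_test(
    ens_ref: Ensemble,
    ens_alt: Ensemble,
    locus_pairs: Sequence[tuple],
    liftover=None,
) -> list[DistanceComparison]:
    """Per-pair 3D distance distributions and two-sided rank-sum p.

    Each item of ``locus_pairs`` is ``(name, locus_a, locus_b)`` or
    ``(name, locus_a, [locus_b1, ...])`` for mean-distance aggregation;
    loci are (chrom, pos) in the reference frame. ``liftover`` (per-chrom
    dict from :func:`loopforge.rewrite.individualize`) maps loci into the
    altered ensemble's frame.
    """
    results = []
    for item in locus_pairs:
        name, locus_a, locus_b = item
        rest = list(locus_b) if isinstance(locus_b, list) else [locus_b]
        ref_loci = [locus_a] + rest

        def lift(locus):
            if liftover is None:
                return locus
            chrom, pos = locus
            mapper = liftover.get(chrom)
            return (chrom, mapper.forward(pos) if mapper else pos)

        alt_loci = [lift(x) for x in ref_loci]
        ref_d = _pair_distances(ens_ref, ref_loci)
        alt_d = _pair_distances(ens_alt, alt_loci)
        if np.all(ref_d == ref_d[0]) and np.all(alt_d == alt_d[0]) and \
                ref_d[0] == alt_d[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(ref_d, alt_d,
                                         alternative="two-sided").pvalue)
        q_ref = np.percentile(ref_d, [25, 50, 75])
        q_alt = np.percentile(alt_d, [25, 50, 75])
        results.append(DistanceComparison(
            name=name, ref_distances=ref_d, alt_distances=alt_d,
            ref_median=float(q_ref[1]), alt_median=float(q_alt[1]),
            ref_iqr=float(q_ref[2] - q_ref[0]),
            alt_iqr=float(q_alt[2] - q_alt[0]),
            p_value=p,
        ))
    return results
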