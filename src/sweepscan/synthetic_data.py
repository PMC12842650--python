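"""Forward Wright-Fisher simulation of phased haplotypes, and VCF fixtures.

The generator produces exactly the statistical structure the scan assumes:
phased biallelic haplotype matrices with known ancestral alleles (0 by
construction, infinite-sites mutation), realistic LD decay (crossovers at
Poisson(r*L) uniform positions per transmitted haplotype), hard selective
sweeps of tunable strength (genic selection: parent haplotypes carrying
the sweep allele are sampled with weight 1+s, the allele introduced as a
single copy after burn-in and the attempt restarted on loss), and
two-population drift divergence (an equilibrium population copied into two
lineages that then evolve independently, with expected neutral per-site
FST of 1 - (1 - 1/(2N))^T after T generations).

Everything is driven by one seed through counter-based stream splitting
(:func:`replicate_rng`), so any replicate is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import HaplotypeMatrix, SweepSimParams

logger = logging.getLogger(__name__)


def replicate_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for (seed, replicate-key) via SeedSequence."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class _PopState:
    """Segregating sites of one population: positions sorted ascending."""

    n_hap: int
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    alleles: np.ndarray = None  # (n_hap, S) uint8

    def __post_init__(self):
        if self.alleles is None:
            self.alleles = np.zeros((self.n_hap, 0), dtype=np.uint8)

    def copy(self) -> "_PopState":
        return _PopState(self.n_hap, self.positions.copy(), self.alleles.copy())

    def sweep_col(self, sweep_pos: int) -> Optional[int]:
        hits = np.flatnonzero(self.positions == sweep_pos)
        return int(hits[0]) if hits.size else None

    def sweep_freq(self, sweep_pos: int) -> float:
        j = self.sweep_col(sweep_pos)
        if j is None:
            return 0.0
        return float(self.alleles[:, j].mean())

    def compact(self, params: SweepSimParams, registry: set,
                drop_fixed: bool, recycle_lost: bool) -> None:
        """Purge monomorphic columns; optionally recycle lost positions.

        A lost mutation leaves no descendants, so its site is clean again;
        fixed positions stay blocked forever (their ancestral state has
        flipped).  Recycling is only safe while a single population exists
        (burn-in): after a split, a position lost here may still segregate
        in the sister population.
        """
        sums = self.alleles.sum(axis=0, dtype=np.int64)
        lost = sums == 0
        keep = ~lost
        if drop_fixed:
            fixed = sums == self.n_hap
            if params.s > 0:
                fixed &= self.positions != params.sweep_pos
            keep &= ~fixed
        if recycle_lost:
            for p_lost in self.positions[lost]:
                registry.discard(int(p_lost))
        if not keep.all():
            self.positions = self.positions[keep]
            self.alleles = np.ascontiguousarray(self.alleles[:, keep])

    def sorted_view(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(self.positions, kind="stable")
        return self.positions[order], self.alleles[:, order]


def _init_state(params: SweepSimParams, rng: np.random.Generator,
                registry: set) -> _PopState:
    """Ancestral population state: identical founders or coalescent draw.

    ``init_model="coalescent"`` draws the full population's haplotypes from
    the standard neutral coalescent with recombination at the same N, mu, r
    and L (binary mutations on a discrete genome; sites hit more than once
    are discarded so the 0 = ancestral coding stays exact).  This places the
    population at mutation-drift equilibrium immediately, replacing the
    ~10N founder-burn-in generations; forward Wright-Fisher dynamics apply
    from here on either way.
    """
    if params.init_model == "founders":
        return _PopState(2 * params.N)
    import msprime

    seed_anc = int(rng.integers(1, 2**31 - 1))
    seed_mut = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=params.N, ploidy=2, population_size=params.N,
        sequence_length=params.L, recombination_rate=params.r,
        discrete_genome=True, random_seed=seed_anc)
    ts = msprime.sim_mutations(
        ts, rate=params.mu, model=msprime.BinaryMutationModel(),
        discrete_genome=True, random_seed=seed_mut)
    keep_pos = []
    keep_idx = []
    for site in ts.sites():
        if len(site.mutations) != 1:
            continue
        p = int(site.position) + 1  # 0-based msprime coordinate -> 1-based bp
        if p == params.sweep_pos or p in registry:
            continue
        keep_pos.append(p)
        keep_idx.append(site.id)
    G = ts.genotype_matrix()  # (n_sites, 2N)
    alle = np.ascontiguousarray(G[keep_idx, :].T.astype(np.uint8))
    registry.update(keep_pos)
    state = _PopState(2 * params.N,
                      np.asarray(keep_pos, dtype=np.int64), alle)
    state.compact(params, registry, drop_fixed=True, recycle_lost=True)
    return state


def _step(state: _PopState, params: SweepSimParams, rng: np.random.Generator,
          select: bool, registry: set) -> None:
    """One non-overlapping Wright-Fisher generation, in place.

    Columns are kept *unsorted* during evolution (crossover segment parity
    depends on a column's position, not its storage order); new mutation
    columns are appended at the end and everything is sorted once at
    sampling time.  Monomorphic columns are purged lazily by
    :meth:`_PopState.compact`.
    """
    n = state.n_hap
    pos, alle = state.positions, state.alleles
    S = pos.size
    # --- parent sampling (genic selection weight 1+s per sweep carrier)
    j = state.sweep_col(params.sweep_pos) if (select and params.s > 0) else None
    if j is not None:
        w = 1.0 + params.s * alle[:, j]
        cdf = np.cumsum(w)
        idx1 = np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")
        idx2 = np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")
    else:
        idx1 = rng.integers(0, n, size=n)
        idx2 = rng.integers(0, n, size=n)
    # --- new mutation count (infinite sites: fresh position per mutation)
    total = int(rng.poisson(params.mu * params.L * n))
    new = np.empty((n, S + total), dtype=np.uint8)
    body = new[:, :S]
    body[...] = alle[idx1]
    # --- crossovers: segment parity decides which parent is copied
    n_x = rng.poisson(params.r * params.L, size=n)
    one = np.flatnonzero(n_x == 1)      # single crossover: one vectorized op
    if one.size and S:
        b1 = rng.integers(1, params.L + 1, size=one.size)
        right = pos[None, :] >= b1[:, None]
        body[one] = np.where(right, alle[idx2[one]], body[one])
    for i in np.flatnonzero(n_x >= 2):  # rare: handle per haplotype
        breaks = np.sort(rng.integers(1, params.L + 1, size=n_x[i]))
        odd = (np.searchsorted(breaks, pos, side="right") & 1).astype(bool)
        body[i, odd] = alle[idx2[i], odd]
    # --- place mutations on random offspring at fresh positions
    mut_pos = np.empty(total, dtype=np.int64)
    for k in range(total):              # rejection-sample unused positions
        for _try in range(2000):
            p_new = int(rng.integers(1, params.L + 1))
            if p_new not in registry:
                registry.add(p_new)
                break
        else:
            raise RuntimeError(
                "mutation position space exhausted; increase L or lower mu")
        mut_pos[k] = p_new
    if total:
        tail = new[:, S:]
        tail[...] = 0
        tail[rng.integers(0, n, size=total), np.arange(total)] = 1
    state.positions = np.concatenate([pos, mut_pos])
    state.alleles = new


def _evolve(state: _PopState, params: SweepSimParams, rng, generations: int,
            registry: set, select: bool = False, drop_fixed: bool = True,
            stop_freq: Optional[float] = None,
            recycle_lost: bool = False, compact_every: int = 10
            ) -> tuple[str, int]:
    """Run generations; with ``stop_freq`` watch the sweep allele.

    Returns ``(outcome, generations_run)`` with outcome ``done`` /
    ``hit`` (sweep reached stop_freq) / ``lost`` (sweep allele lost).
    The column store is compacted every ``compact_every`` generations and
    on exit (stale monomorphic columns are harmless in between).
    """
    outcome, ran = "done", generations
    for g in range(generations):
        _step(state, params, rng, select, registry)
        if (g + 1) % compact_every == 0:
            state.compact(params, registry, drop_fixed, recycle_lost)
        if stop_freq is not None:
            f = state.sweep_freq(params.sweep_pos)
            if f <= 0.0:
                outcome, ran = "lost", g + 1
                break
            if f >= stop_freq:
                outcome, ran = "hit", g + 1
                break
    state.compact(params, registry, drop_fixed, recycle_lost)
    return outcome, ran


def _introduce_sweep(state: _PopState, params: SweepSimParams, rng) -> None:
    hap = int(rng.integers(0, state.n_hap))
    col = np.zeros((state.n_hap, 1), dtype=np.uint8)
    col[hap, 0] = 1
    state.positions = np.append(state.positions, params.sweep_pos)
    state.alleles = np.hstack([state.alleles, col])


def _run_sweep(state: _PopState, params: SweepSimParams, rng,
               registry: set, drop_fixed: bool = True) -> tuple[_PopState, int]:
    """Condition the sweep on reaching target_freq (restart on loss)."""
    target = params.target_freq if params.target_freq is not None else 1.0
    base = state.copy()
    for attempt in range(params.max_restarts):
        trial = base.copy()
        _introduce_sweep(trial, params, rng)
        outcome, g = _evolve(trial, params, rng, params.max_sweep_generations,
                             registry, select=True, drop_fixed=drop_fixed,
                             stop_freq=target)
        if outcome == "hit":
            return trial, g
        if outcome == "done":
            raise RuntimeError(
                "sweep did not reach target_freq within the generation cap")
    raise RuntimeError(
        f"sweep allele lost in all {params.max_restarts} attempts")


def _sample_matrix(state: _PopState, params: SweepSimParams, rng,
                   chrom: str, population: str,
                   rows: Optional[np.ndarray] = None) -> HaplotypeMatrix:
    if rows is None:
        rows = np.sort(rng.choice(state.n_hap, size=params.sample_n,
                                  replace=False))
    pos, full = state.sorted_view()
    alle = full[rows, :]
    sums = alle.sum(axis=0)
    seg = (sums > 0) & (sums < rows.size)
    return _as_matrix(pos[seg], alle[:, seg], chrom, population)


def _as_matrix(pos: np.ndarray, alle: np.ndarray, chrom: str,
               population: str) -> HaplotypeMatrix:
    n_hap, n_sites = alle.shape
    owners = [f"{population.lower()}_ind{i // 2}" for i in range(n_hap)]
    return HaplotypeMatrix(
        chrom=chrom,
        positions=pos,
        site_ids=np.array([f"s{p}" for p in pos], dtype=object),
        alleles=alle,
        haplotype_owner=np.array(owners, dtype=object),
        population=np.array([population] * n_hap, dtype=object),
        ancestral_known=np.ones(n_sites, dtype=bool),
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["G"] * n_sites, dtype=object),
        ancestral_is_ref=np.ones(n_sites, dtype=bool),
    )


def simulate_wf(params: SweepSimParams, chrom: str = "1",
                population: str = "POP1") -> HaplotypeMatrix:
    """Single-population Wright-Fisher sample, neutral or with a hard sweep.

    With ``s > 0`` the sweep allele at ``sweep_pos`` is introduced as one
    copy after burn-in and conditioned (by restarting) on reaching
    ``target_freq`` (fixation if unset); the sample is drawn the moment the
    condition is met.  Deterministic given ``params.seed``.
    """
    rng = replicate_rng(params.seed)
    registry = {params.sweep_pos}
    state = _init_state(params, rng, registry)
    _evolve(state, params, rng, params.burn_in, registry, select=False,
            recycle_lost=True)
    if params.s > 0 or params.target_freq is not None:
        state, _ = _run_sweep(state, params, rng, registry)
    return _sample_matrix(state, params, rng, chrom, population)


def simulate_split(params: SweepSimParams, chrom: str = "1",
                   pop_names: tuple[str, str] = ("POP1", "POP2"),
                   sweep_in_first: Optional[bool] = None
                   ) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Two populations diverged from one equilibrium ancestor.

    Both lineages evolve ``split_T`` generations after the split.  With
    ``s > 0`` (or ``sweep_in_first=True``) the sweep allele is introduced
    in the first population at the split and conditioned on reaching
    ``target_freq``; the second population then drifts neutrally for the
    same number of generations, so the two samples are contemporaneous.
    Returns two matrices over the union of segregating site sets.
    """
    rng = replicate_rng(params.seed)
    registry = {params.sweep_pos}
    anc = _init_state(params, rng, registry)
    _evolve(anc, params, rng, params.burn_in, registry, select=False,
            recycle_lost=True)
    pop1 = anc.copy()
    pop2 = anc
    do_sweep = sweep_in_first if sweep_in_first is not None else params.s > 0
    if do_sweep:
        pop1, gens = _run_sweep(pop1, params, rng, registry, drop_fixed=False)
        # the sweep path sets the clock; both samples are drawn at its end
        _evolve(pop2, params, rng, gens, registry, select=False,
                drop_fixed=False)
    else:
        _evolve(pop1, params, rng, params.split_T, registry, select=False,
                drop_fixed=False)
        _evolve(pop2, params, rng, params.split_T, registry, select=False,
                drop_fixed=False)
    rows1 = np.sort(rng.choice(pop1.n_hap, params.sample_n, replace=False))
    rows2 = np.sort(rng.choice(pop2.n_hap, params.sample_n, replace=False))
    a1, a2 = pop1.alleles[rows1, :], pop2.alleles[rows2, :]
    union = np.union1d(pop1.positions, pop2.positions)
    full1 = np.zeros((a1.shape[0], union.size), dtype=np.uint8)
    full2 = np.zeros((a2.shape[0], union.size), dtype=np.uint8)
    full1[:, np.searchsorted(union, pop1.positions)] = a1
    full2[:, np.searchsorted(union, pop2.positions)] = a2
    tot = full1.sum(axis=0) + full2.sum(axis=0)
    seg = (tot > 0) & (tot < full1.shape[0] + full2.shape[0])
    return (_as_matrix(union[seg], full1[:, seg], chrom, pop_names[0]),
            _as_matrix(union[seg], full2[:, seg], chrom, pop_names[1]))


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture_vcf(matrix: HaplotypeMatrix, path: str) -> None:
    """Write a matrix as a plain phased VCF with the true AA annotation.

    Haplotype rows group by owner into diploid (two rows) or hemizygous
    (one row) samples; any owner with more than two rows is an error.
    ``read_phased_vcf(write_fixture_vcf(m))`` reproduces the allele table
    exactly.
    """
    owners: list[str] = []
    rows_of: dict[str, list[int]] = {}
    for i, o in enumerate(matrix.haplotype_owner):
        if o not in rows_of:
            owners.append(o)
            rows_of[o] = []
        rows_of[o].append(i)
    for o, rows in rows_of.items():
        if len(rows) > 2:
            raise ValueError(f"sample {o!r} owns {len(rows)} haplotype rows")
    ref = matrix.ref_allele
    alt = matrix.alt_allele
    if ref is None or alt is None:
        ref = np.array(["A"] * matrix.n_sites, dtype=object)
        alt = np.array(["G"] * matrix.n_sites, dtype=object)
    anc_is_ref = matrix.ancestral_is_ref
    aa = np.where(anc_is_ref, ref, alt)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(o) for o in owners) + "\n")
        for j in range(matrix.n_sites):
            flip = not anc_is_ref[j]
            gts = []
            for o in owners:
                vals = [int(matrix.alleles[i, j]) ^ flip
                        for i in rows_of[o]]
                gts.append("|".join(str(v) for v in vals))
            fh.write("\t".join([
                str(matrix.chrom), str(int(matrix.positions[j])),
                str(matrix.site_ids[j]), str(ref[j]), str(alt[j]),
                ".", "PASS", f"AA={aa[j]}", "GT", *gts]) + "\n")


def write_panel(matrix: HaplotypeMatrix, path: str) -> None:
    """Write the sample->population panel TSV matching a fixture VCF."""
    seen: dict[str, str] = {}
    for o, p in zip(matrix.haplotype_owner, matrix.population):
        seen.setdefault(str(o), str(p))
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for o, p in seen.items():
            fh.write(f"{o}\t{p}\n")
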