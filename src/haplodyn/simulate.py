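"""Synthetic breeding-program genotype panels with known truth.

The generator emulates the study design the analyses assume: a panel of
inbred (haploid-equivalent) accessions over three breeding phases on 12
chromosomes. Phase-1 accessions (landraces) are drawn from a small number of
diverged ancestral pools (Balding-Nichols allele frequencies, mosaic
haplotypes). Phase-2 and phase-3 cultivars descend from a bottlenecked
founder subset by pedigree-recorded crosses with Poisson crossovers (thinned
x0.1 inside one centromere-like interval per chromosome), with skewed reuse
of elite parents. Novel polymorphisms are injected as SNP mutations on
breeding lineages at a clock rate derived from ``novel_accrual_rate`` (new
haplotype-block polymorphisms per registration year; one SNP mutation
perturbs ~``window`` five-SNP windows) and then propagate by crossing, so
their population frequency can rise between phases without being hard-coded.
Missing/heterozygote noise is applied last; a given seed is fully
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .blocks import DEFAULT_WINDOW, census_all, enumerate_blocks
from .model import MISSING, DataError, GenotypeMatrix, build_matrix

log = logging.getLogger(__name__)


def default_snps_per_chromosome(total: int = 3259,
                                n_chromosomes: int = 12) -> tuple[int, ...]:
    base, extra = divmod(total, n_chromosomes)
    return tuple(base + (1 if c < extra else 0) for c in range(n_chromosomes))


@dataclass
class SimConfig:
    """Study-design parameters of the simulated breeding program.

    Defaults mirror the panel the analyses target: 12 chromosomes of about
    31.7 Mb (genome ~380 Mb) carrying 3259 SNPs in total; irrigated group
    sizes 41/50/63 plus 22/1/0 non-irrigated accessions (177 in all);
    registration years 1931-2005; an accrual rate of 3 new haplotype-block
    polymorphisms per year.
    """

    n_chromosomes: int = 12
    snps_per_chromosome: tuple[int, ...] = field(
        default_factory=default_snps_per_chromosome)
    chromosome_length_bp: int = 31_700_000
    n_ancestral_pools: int = 4
    pool_divergence: float = 0.35        # Fst-like
    group_sizes: tuple[int, int, int] = (41, 50, 63)        # irrigated
    non_irrigated_sizes: tuple[int, int, int] = (22, 1, 0)
    founder_counts_per_phase: tuple[int, int] = (12, 10)    # bottleneck severity
    crossovers_per_chromosome: float = 0.4                  # Poisson mean/meiosis
    parent_reuse: float = 0.6      # P(parent drawn from earlier same-phase lines)
    backcross_rate: float = 0.15   # P(a cross is followed by a recurrent backcross)
    novel_accrual_rate: float = 3.0   # new block polymorphisms per year
    year_range: tuple[int, int] = (1931, 2005)
    phase2_year_range: tuple[int, int] = (1931, 1974)
    phase3_year_range: tuple[int, int] = (1975, 2005)
    window: int = DEFAULT_WINDOW
    missing_rate: float = 0.01
    het_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if len(self.snps_per_chromosome) != self.n_chromosomes:
            raise DataError("snps_per_chromosome length != n_chromosomes")
        if any(n < self.window for n in self.snps_per_chromosome):
            raise DataError(f"every chromosome needs >= {self.window} SNPs")
        for p in (self.missing_rate, self.het_rate, self.parent_reuse,
                  self.backcross_rate):
            if not 0.0 <= p <= 1.0:
                raise DataError(f"probability {p} outside [0, 1]")
        if not 0.0 < self.pool_divergence < 1.0:
            raise DataError("pool_divergence must be in (0, 1)")
        if any(g < 1 for g in self.group_sizes):
            raise DataError("group sizes must be >= 1")
        if any(g < 0 for g in self.non_irrigated_sizes):
            raise DataError("non-irrigated sizes must be >= 0")
        if (self.founder_counts_per_phase[0] > self.group_sizes[0]
                or self.founder_counts_per_phase[1] > self.group_sizes[1]):
            raise DataError("founder counts exceed the phase group sizes")
        if self.novel_accrual_rate < 0:
            raise DataError("novel_accrual_rate must be >= 0")
        if self.n_ancestral_pools < 1:
            raise DataError("need >= 1 ancestral pool")


@dataclass
class SimTruth:
    """Ground truth of one simulated panel."""

    q_matrix: pd.DataFrame          # accession x ancestral pool, rows sum to 1
    pedigree: pd.DataFrame          # child, parent1, parent2, recurrent_parent
    novel_snps: pd.DataFrame        # snp_id, year, accession (lineage of origin)
    block_counts: pd.DataFrame      # pre-noise per-block distinct counts per group
    het_mask: np.ndarray            # cells corrupted as heterozygote calls
    centromeres: pd.DataFrame       # chromosome, start_bp, end_bp
    config: SimConfig


# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=2 * n + 10))
    while pos.size < n:
        pos = np.unique(np.concatenate(
            [pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _recombine(rng: np.random.Generator, hap_a: np.ndarray, hap_b: np.ndarray,
               chrom_idx: np.ndarray, positions: np.ndarray,
               config: SimConfig, centro: np.ndarray) -> np.ndarray:
    """One meiosis product of two whole-genome haplotypes.

    Crossover counts are Poisson per chromosome; a crossover landing inside
    the centromere-like interval is kept with probability 0.1 (recombination
    suppression). Segments alternate between parents starting from a random
    one.
    """
    child = np.empty_like(hap_a)
    for c in range(config.n_chromosomes):
        sel = chrom_idx == c
        pos = positions[sel]
        n_x = rng.poisson(config.crossovers_per_chromosome)
        cuts = []
        for _ in range(n_x):
            x = rng.integers(1, config.chromosome_length_bp)
            lo, hi = centro[c]
            if lo <= x <= hi and rng.random() >= 0.1:
                continue
            cuts.append(x)
        current = rng.integers(0, 2)
        source = np.full(sel.sum(), current)
        for cut in sorted(cuts):
            current = 1 - current
            source[pos > cut] = current
        a, b = hap_a[sel], hap_b[sel]
        child[sel] = np.where(source == 0, a, b)
    return child


def simulate_panel(config: SimConfig | None = None,
                   seed: int | None = None) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate one breeding-program panel; identical seed, identical output."""
    config = config or SimConfig()
    config.validate()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    # -- map ---------------------------------------------------------------
    chrom_idx = np.concatenate([
        np.full(n, c) for c, n in enumerate(config.snps_per_chromosome)])
    positions = np.concatenate([
        _draw_positions(rng, n, config.chromosome_length_bp)
        for n in config.snps_per_chromosome])
    n_snps = len(positions)
    L = config.chromosome_length_bp
    centro = np.stack([(int(0.40 * L), int(0.55 * L))
                       for _ in range(config.n_chromosomes)])

    # -- ancestral pools (Balding-Nichols) --------------------------------
    # U-shaped ancestral spectrum: a realistic site-frequency spectrum whose
    # near-fixed tail supplies sites monomorphic in phase 1, the substrate
    # for later novel mutations
    F = config.pool_divergence
    p_anc = 0.01 + 0.98 * rng.beta(0.3, 0.3, size=n_snps)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    pool_freq = np.stack([rng.beta(a, b) for _ in range(config.n_ancestral_pools)])

    n_pools = config.n_ancestral_pools
    irr_pools = list(range(max(1, n_pools - 1)))   # last pool ~ non-irrigated
    upland_pool = n_pools - 1

    def draw_landrace(main_pool: int) -> tuple[np.ndarray, np.ndarray]:
        """Mosaic haplotype from the pools; returns (haplotype, pool of each SNP)."""
        pool_of = np.empty(n_snps, dtype=np.int64)
        for c in range(config.n_chromosomes):
            sel = chrom_idx == c
            pos = positions[sel]
            n_seg = 1 + rng.poisson(1.0)
            cuts = np.sort(rng.integers(1, L, size=n_seg - 1))
            seg = np.searchsorted(cuts, pos)
            seg_pool = np.where(rng.random(n_seg) < 0.8, main_pool,
                                rng.integers(0, n_pools, size=n_seg))
            pool_of[sel] = seg_pool[seg]
        hap = (rng.random(n_snps)
               < pool_freq[pool_of, np.arange(n_snps)]).astype(np.int8)
        return hap, pool_of

    # -- phase 1 -----------------------------------------------------------
    haps: dict[str, np.ndarray] = {}
    acc_rows: list[dict] = []
    q_rows: dict[str, np.ndarray] = {}

    def add_landraces(n: int, prefix: str, pools: list[int], regime: str,
                      group: str) -> list[str]:
        ids = []
        for i in range(n):
            name = f"{prefix}{i + 1:03d}"
            main = pools[rng.integers(0, len(pools))]
            hap, pool_of = draw_landrace(main)
            haps[name] = hap
            q = np.bincount(pool_of, minlength=n_pools) / n_snps
            q_rows[name] = q
            acc_rows.append({"accession_id": name, "group": group,
                             "water_regime": regime,
                             "registration_year": None, "region": None})
            ids.append(name)
        return ids

    g1_irr = add_landraces(config.group_sizes[0], "LR", irr_pools,
                           "irrigated", "group1")
    g1_non = add_landraces(config.non_irrigated_sizes[0], "UP",
                           [upland_pool], "non_irrigated", "group1")

    # -- mutation bookkeeping ---------------------------------------------
    # sites monomorphic among all phase-1 haplotypes are eligible for novel
    # mutations; each mutation site is used once
    phase1 = np.stack([haps[n] for n in g1_irr + g1_non])
    mono = np.flatnonzero((phase1 == phase1[0]).all(axis=0))
    mutable = list(rng.permutation(mono))
    # mutation clock calibration: the accrual parameter is the expected
    # observable block-polymorphism accrual per year, and one SNP mutation is
    # observable in the windows that contain it (w per interior site, fewer
    # at chromosome ends) and only where the carrier's window is complete
    # under the missing/het corruption applied later
    w = config.window
    incidences = sum(w * max(0, n - w + 1) for n in config.snps_per_chromosome)
    windows_per_site = incidences / n_snps
    q_obs = (1.0 - config.missing_rate - config.het_rate) ** w
    # two carried mutations landing in one window yield fewer novel windows
    # than two isolated ones; at the mean registration year a cultivar
    # carries ~mu x (mean year - start) mutant sites, thinning the
    # per-mutation window yield by (1 - M/n)^(w-1); solve by fixed point
    y0 = float(config.year_range[0])
    n2, n3 = config.group_sizes[1], config.group_sizes[2]
    mean_year = (n2 * sum(config.phase2_year_range) / 2
                 + n3 * sum(config.phase3_year_range) / 2) / (n2 + n3)
    mu_snp = 0.0
    if windows_per_site * q_obs > 0 and config.novel_accrual_rate > 0:
        mu_snp = config.novel_accrual_rate / (windows_per_site * q_obs)
        for _ in range(8):
            m_bar = mu_snp * max(0.0, mean_year - y0)
            collision = max(1e-6, (1.0 - min(0.5, m_bar / n_snps)) ** (w - 1))
            mu_snp = config.novel_accrual_rate / (
                windows_per_site * q_obs * collision)  # SNP mutations/year
    novel_records: list[dict] = []
    ped_rows: list[dict] = []

    def breed(name: str, year: int, parents: list[str],
              parent_years: dict[str, float]) -> None:
        p1, p2 = parents
        child = _recombine(rng, haps[p1], haps[p2], chrom_idx, positions,
                           config, centro)
        recurrent = ""
        if rng.random() < config.backcross_rate:
            # backcross to parent 1 (the recurrent parent)
            child = _recombine(rng, child, haps[p1], chrom_idx, positions,
                               config, centro)
            recurrent = p1
        ped_rows.append({"child": name, "parent1": p1, "parent2": p2,
                         "recurrent_parent": recurrent})
        dt = max(0.0, year - (parent_years[p1] + parent_years[p2]) / 2.0)
        n_mut = rng.poisson(mu_snp * dt)
        if n_mut > len(mutable):
            log.warning("mutable-site pool exhausted; %d injections dropped",
                        n_mut - len(mutable))
        for _ in range(min(n_mut, len(mutable))):
            site = mutable.pop()
            child[site] = 1 - child[site]
            novel_records.append({"snp_id": f"snp{site + 1:05d}",
                                  "year": year, "accession": name})
        haps[name] = child
        q_rows[name] = (q_rows[p1] + q_rows[p2]) / 2.0
        parent_years[name] = year

    def breed_phase(group: str, prefix: str, n: int, founders: list[str],
                    year_lo: int, year_hi: int,
                    parent_years: dict[str, float]) -> list[str]:
        years = np.sort(rng.integers(year_lo, year_hi + 1, size=n))
        # skewed reuse of elite founders (a few dominate the crossing program)
        w = rng.dirichlet(np.full(len(founders), 0.5))
        created: list[str] = []
        for i in range(n):
            name = f"{prefix}{i + 1:03d}"
            parents = []
            while len(parents) < 2:
                if created and rng.random() < config.parent_reuse:
                    # breeders cross recent elite material: draw among the
                    # latest registered lines, keeping the mutation clock's
                    # parent-child gap near the development period
                    k = min(10, len(created))
                    cand = created[len(created) - 1 - rng.integers(0, k)]
                else:
                    cand = founders[rng.choice(len(founders), p=w)]
                if cand not in parents:
                    parents.append(cand)
                elif len(founders) + len(created) < 2:
                    parents.append(cand)  # degenerate tiny configs
            breed(name, int(years[i]), parents, parent_years)
            acc_rows.append({"accession_id": name, "group": group,
                             "water_regime": "irrigated",
                             "registration_year": int(years[i]),
                             "region": None})
            created.append(name)
        return created

    parent_years: dict[str, float] = {
        n: float(config.year_range[0]) for n in g1_irr + g1_non}

    # -- phase 2: bottlenecked founders from phase 1 ----------------------
    f2 = [g1_irr[i] for i in rng.choice(len(g1_irr),
                                        size=config.founder_counts_per_phase[0],
                                        replace=False)]
    g2_irr = breed_phase("group2", "EC", config.group_sizes[1], f2,
                         *config.phase2_year_range, parent_years)
    add_landraces(config.non_irrigated_sizes[1], "UPX", [upland_pool],
                  "non_irrigated", "group2")

    # -- phase 3: founders biased toward late elite phase-2 cultivars -----
    n_f3 = config.founder_counts_per_phase[1]
    order = np.argsort([parent_years[n] for n in g2_irr])
    late_half = [g2_irr[i] for i in order[len(order) // 2:]]
    pool3 = late_half if len(late_half) >= n_f3 else g2_irr
    f3 = [pool3[i] for i in rng.choice(len(pool3), size=n_f3, replace=False)]
    g3_irr = breed_phase("group3", "MC", config.group_sizes[2], f3,
                         *config.phase3_year_range, parent_years)
    if config.non_irrigated_sizes[2]:
        add_landraces(config.non_irrigated_sizes[2], "UPY", [upland_pool],
                      "non_irrigated", "group3")

    # -- assemble ----------------------------------------------------------
    acc = pd.DataFrame(acc_rows)
    acc["registration_year"] = acc["registration_year"].astype("Int64")
    snps = pd.DataFrame({
        "snp_id": [f"snp{i + 1:05d}" for i in range(n_snps)],
        "chromosome": chrom_idx + 1,
        "position_bp": positions,
        "source_panel": rng.choice(["koshihikari", "eiko", "rikuu132"],
                                   size=n_snps, p=[0.64, 0.15, 0.21]),
    })
    clean = np.stack([haps[n] for n in acc["accession_id"]]).astype(np.int8)

    clean_matrix = build_matrix(acc, snps, clean)
    groups = {g: clean_matrix.group_rows(g) for g in ("group1", "group2", "group3")}
    block_counts = census_all(clean_matrix, groups,
                              enumerate_blocks(clean_matrix.snps, config.window))

    # -- missing / het corruption (both stored as missing) -----------------
    calls = clean_matrix.calls.copy()
    noise = rng.random(calls.shape)
    miss = noise < config.missing_rate
    het = (noise >= config.missing_rate) & (noise < config.missing_rate
                                            + config.het_rate)
    calls[miss | het] = MISSING
    matrix = GenotypeMatrix(clean_matrix.accessions, clean_matrix.snps, calls)

    q = pd.DataFrame([q_rows[n] for n in acc["accession_id"]],
                     index=acc["accession_id"],
                     columns=[f"pool{k + 1}" for k in range(n_pools)])
    q = q.div(q.sum(axis=1), axis=0)
    truth = SimTruth(
        q_matrix=q,
        pedigree=pd.DataFrame(ped_rows, columns=["child", "parent1",
                                                 "parent2", "recurrent_parent"]),
        novel_snps=pd.DataFrame(novel_records,
                                columns=["snp_id", "year", "accession"]),
        block_counts=block_counts,
        het_mask=het,
        centromeres=pd.DataFrame({
            "chromosome": np.arange(1, config.n_chromosomes + 1),
            "start_bp": centro[:, 0], "end_bp": centro[:, 1]}),
        config=config,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def toy_config(seed: int = 0) -> SimConfig:
    """A 2-chromosome miniature used by unit tests and docs."""
    return SimConfig(
        n_chromosomes=2, snps_per_chromosome=(14, 9),
        chromosome_length_bp=2_000_000, n_ancestral_pools=3,
        group_sizes=(8, 8, 8), non_irrigated_sizes=(2, 0, 0),
        founder_counts_per_phase=(4, 4), crossovers_per_chromosome=0.8,
        novel_accrual_rate=3.0, missing_rate=0.02, het_rate=0.01, seed=seed)


def emit_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small, fully parseable fixture set: toy genotype panel (with
    one chromosome truncated to 4 SNPs, i.e. below the window size), its
    metadata, pedigree, Q-matrix, an annotation BED, and a truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_panel(toy_config(seed))
    # keep 4 SNPs on the last chromosome: no five-SNP block can be formed there
    last = matrix.snps["chromosome"].max()
    idx_last = np.flatnonzero((matrix.snps["chromosome"] == last).to_numpy())
    keep = np.concatenate([
        np.flatnonzero((matrix.snps["chromosome"] != last).to_numpy()),
        idx_last[:4]])
    matrix = matrix.subset_snps(np.sort(keep))

    paths = hio.write_matrix(matrix, out_dir, prefix="toy")
    paths["pedigree"] = out_dir / "toy_pedigree.tsv"
    hio.write_pedigree(truth.pedigree, paths["pedigree"])
    paths["qmatrix"] = out_dir / "toy_qmatrix.tsv"
    truth.q_matrix.to_csv(paths["qmatrix"], sep="\t")
    paths["annotations"] = out_dir / "toy_annotations.bed"
    hio.write_bed(_toy_annotations(matrix), paths["annotations"])
    paths["truth"] = out_dir / "toy_truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump({"novel_snps": truth.novel_snps.to_dict("records"),
                   "centromeres": truth.centromeres.to_dict("records"),
                   "seed": truth.config.seed}, fh, indent=1)
    return paths


def _toy_annotations(matrix: GenotypeMatrix):
    from .model import AnnotationInterval
    mid = int(matrix.snps["position_bp"].median())
    return [AnnotationInterval(1, max(1, mid - 50_000), mid + 50_000,
                               "qtl_demo", "qtl"),
            AnnotationInterval(1, 800_000, 1_100_000, "centromere_demo",
                               "centromere")]
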