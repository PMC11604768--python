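"""Synthetic ground-truth data with the statistical structure of an MPRA.

The generator emulates: a plasmid library with skewed per-promoter barcode
representation (log-normal counts targeting mean 82 / median 65), barcode
copy proportions drawn from a Dirichlet within each promoter, overdispersed
DNA counts, RNA counts proportional to per-promoter condition-dependent
transcription rates (baseline rates log-uniform over a >=300-fold span),
substitution sequencing errors in barcodes, and spike-in reads.  It does not
emulate PCR jackpotting, index hopping, or quality-score error profiles.

Two entry points: :func:`simulate_counts` produces count matrices directly
(for the quantification and differential stages); :func:`simulate_screen`
additionally emits dictionary read pairs and per-sample FASTQ reads so the
read-level stages can be tested against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import DesignConfig, MIN_PROMOTERS, TreUnit, unit_core
from .dictionary import BARCODE_LEN, levenshtein
from .motifs import BASES, BindingMotif, PwmSeed
from .quantify import CountMatrix

#: IUPAC degenerate codes usable for planted degeneracy, keyed by base set.
_DEGENERATE_FOR = {
    "A": "RWM", "C": "YSM", "G": "RSK", "T": "YWK",
}


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_motifs: int = 50
    motif_length_range: tuple = (6, 20)
    n_containments: int = 0
    # per-promoter barcode representation (log-normal, rounded, floor 1)
    barcode_mean: float = 82.0
    barcode_median: float = 65.0
    n_barcodes_per_promoter: int | None = None  # overrides the distribution
    dna_depth: float = 80.0  # mean reads per barcode in the plasmid library
    rna_depth: float = 80.0  # mean reads per barcode at baseline rate 1
    nb_dispersion: float = 0.2
    rate_fold_range: float = 300.0  # span of the log-uniform baseline rates
    responsive_fraction: float = 0.0
    effect_size: float = 2.0  # fold-change magnitude of responsive promoters
    effect_direction: str = "both"  # both | up | down
    substitution_error_rate: float = 0.001
    dictionary_error_rate: float = 0.0
    spike_in_fraction: float = 0.05
    n_spike_refs: int = 3
    n_dna_replicates: int = 3
    n_rna_replicates: int = 3
    sample_depth_sigma: float = 0.15  # lognormal sd of per-sample depth
    dictionary_reads_per_barcode: int = 3
    read_tail_length: int = 12
    barcode_min_separation: int = 3  # pairwise Levenshtein floor

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_error_rate <= 0.05:
            raise ValueError("substitution_error_rate must lie in [0, 0.05]")
        for name in ("barcode_mean", "barcode_median", "dna_depth", "rna_depth",
                     "rate_fold_range", "effect_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_direction not in ("both", "up", "down"):
            raise ValueError("effect_direction must be both, up or down")
        if self.barcode_mean < self.barcode_median:
            raise ValueError("log-normal requires mean >= median")


@dataclass
class GroundTruth:
    """The generator's hidden state, used as the test oracle."""

    barcode_to_promoter: dict
    baseline_rate: pd.Series  # per promoter
    effects: pd.DataFrame  # promoter x condition multipliers
    copy_proportions: pd.Series  # per barcode, within-promoter plasmid share
    sample_depth: pd.Series | None = None  # true per-sample depth multipliers
    seed: int = 0


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _barcode_counts(rng, n: int, config: SimulationConfig) -> np.ndarray:
    """Per-promoter barcode representation: rounded log-normal, floor 1."""
    if config.n_barcodes_per_promoter is not None:
        return np.full(n, config.n_barcodes_per_promoter, dtype=int)
    mu = np.log(config.barcode_median)
    sigma = np.sqrt(2.0 * np.log(config.barcode_mean / config.barcode_median))
    draws = rng.lognormal(mu, sigma, size=n)
    return np.maximum(1, np.round(draws)).astype(int)


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, float), 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


# ---------------------------------------------------------------------------
# Catalog simulation


def simulate_catalog(
    config: SimulationConfig, seed: int = 0
) -> tuple[list[PwmSeed], list[BindingMotif]]:
    """Generate PWM seeds with a known expected post-deduplication catalog.

    Seeds carry flanking Ns and internal degenerate codes whose PWM argmax
    equals the planted consensus base; ``config.n_containments`` seeds are
    planted as substrings of other motifs and are expected to be removed.
    Accidental containments between independent motifs are redrawn away, so
    the expected catalog is exact by construction.
    """
    if config.n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    rng = np.random.default_rng([seed, 101])
    lo, hi = config.motif_length_range
    forbidden = DesignConfig().forbidden_sites
    motifs: list[str] = []
    while len(motifs) < config.n_motifs:
        seq = _rand_seq(rng, int(rng.integers(lo, hi + 1)))
        if any(site in seq for site in forbidden):
            continue
        if any(seq in m or m in seq for m in motifs):
            continue
        motifs.append(seq)
    n_cont = min(config.n_containments, config.n_motifs - 1)
    contained_idx = set()
    if n_cont:
        hosts = sorted(range(len(motifs)), key=lambda i: -len(motifs[i]))[:n_cont]
        victims = [i for i in range(len(motifs)) if i not in hosts]
        rng.shuffle(victims)
        for host, victim in zip(hosts, victims):
            h = motifs[host]
            sub_len = int(rng.integers(4, max(5, len(h) - 1)))
            start = int(rng.integers(0, len(h) - sub_len + 1))
            motifs[victim] = h[start:start + sub_len]
            contained_idx.add(victim)

    seeds, expected = [], []
    for i, seq in enumerate(motifs):
        tf = f"TF{i:03d}"
        chars, rows = [], []
        n5, n3 = rng.integers(0, 3), rng.integers(0, 3)
        for _ in range(n5):
            chars.append("N")
            rows.append([0.25] * 4)
        for c in seq:
            if rng.random() < 0.2:  # plant an internal degenerate position
                code = _DEGENERATE_FOR[c][rng.integers(0, 3)]
                chars.append(code)
                row = [0.4 / 3] * 4
                row[BASES.index(c)] = 0.6
                rows.append(row)
            else:
                chars.append(c)
                row = [0.0] * 4
                row[BASES.index(c)] = 1.0
                rows.append(row)
        for _ in range(n3):
            chars.append("N")
            rows.append([0.25] * 4)
        seeds.append(PwmSeed(tf, "synthetic", "".join(chars), np.array(rows)))
        if i not in contained_idx:
            expected.append(
                BindingMotif(f"M{i:04d}_{tf}", tf, seq, "experimental")
            )
    return seeds, expected


# ---------------------------------------------------------------------------
# Count-level simulation


def _draw_promoter_params(rng, promoter_ids, config, conditions):
    n = len(promoter_ids)
    half = np.log(config.rate_fold_range) / 2.0
    rates = pd.Series(np.exp(rng.uniform(-half, half, size=n)), index=promoter_ids)
    effects = pd.DataFrame(1.0, index=promoter_ids, columns=list(conditions))
    n_resp = int(round(config.responsive_fraction * n))
    if n_resp and len(conditions) > 1:
        responsive = rng.choice(n, size=n_resp, replace=False)
        if config.effect_direction == "up":
            mult = np.full(n_resp, config.effect_size)
        elif config.effect_direction == "down":
            mult = np.full(n_resp, 1.0 / config.effect_size)
        else:  # realistic screens respond in both directions
            sign = rng.random(n_resp) < 0.5
            mult = np.where(sign, config.effect_size, 1.0 / config.effect_size)
        for cond in conditions[1:]:
            effects.iloc[responsive, effects.columns.get_loc(cond)] = mult
    return rates, effects


def _sample_meta(config, conditions):
    rows = []
    for b in range(config.n_dna_replicates):
        rows.append((f"dna_{b + 1}", "DNA", "input", f"batch{b + 1}"))
    for cond in conditions:
        for b in range(config.n_rna_replicates):
            rows.append((f"rna_{cond}_{b + 1}", "RNA", cond, f"batch{b + 1}"))
    return pd.DataFrame(rows, columns=["sample_id", "material", "condition", "batch"])


def simulate_counts(
    config: SimulationConfig,
    n_promoters: int,
    conditions=("ctrl", "treat"),
    effects: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[GroundTruth, CountMatrix]:
    """Draw a DNA/RNA count matrix with known per-promoter rates.

    Barcode copy proportions are Dirichlet within each promoter; DNA counts
    are NB(mean = dna_depth x copy share x n_barcodes x sample depth); RNA
    counts additionally scale with the promoter's baseline rate and its
    condition effect.  ``effects`` may be supplied to override the drawn
    condition multipliers (index = promoter ids, columns = conditions).
    """
    rng = np.random.default_rng([seed, 202])
    promoter_ids = [f"P{i:05d}" for i in range(n_promoters)]
    n_bc = _barcode_counts(rng, n_promoters, config)
    total_bc = int(n_bc.sum())
    barcodes = _unique_barcodes(rng, total_bc)
    bc_to_prom, props = {}, np.empty(total_bc)
    pos = 0
    for pid, k in zip(promoter_ids, n_bc):
        p = rng.dirichlet(np.ones(k))
        props[pos:pos + k] = p
        for j in range(k):
            bc_to_prom[barcodes[pos + j]] = pid
        pos += k
    rates, drawn_effects = _draw_promoter_params(rng, promoter_ids, config, conditions)
    if effects is not None:
        drawn_effects = effects.reindex(index=promoter_ids, columns=list(conditions))
        if drawn_effects.isna().any().any():
            raise ValueError("effects must cover every promoter and condition")
    meta = _sample_meta(config, conditions)
    depth_mult = np.exp(
        rng.normal(0.0, config.sample_depth_sigma, size=len(meta))
    )
    prom_per_bc = np.repeat(np.arange(n_promoters), n_bc)
    scale_bc = props * np.repeat(n_bc, n_bc)  # copy share x promoter size
    rate_bc = rates.to_numpy()[prom_per_bc]
    values = np.empty((total_bc, len(meta)), dtype=np.int64)
    for s, row in enumerate(meta.itertuples(index=False)):
        if row.material == "DNA":
            mean = config.dna_depth * scale_bc * depth_mult[s]
        else:
            eff = drawn_effects[row.condition].to_numpy()[prom_per_bc]
            mean = config.rna_depth * scale_bc * rate_bc * eff * depth_mult[s]
        values[:, s] = _nb_draw(rng, mean, config.nb_dispersion)
    counts = CountMatrix(
        values=pd.DataFrame(values, index=barcodes, columns=meta["sample_id"]),
        meta=meta,
    )
    truth = GroundTruth(
        barcode_to_promoter=bc_to_prom,
        baseline_rate=rates,
        effects=drawn_effects,
        copy_proportions=pd.Series(props, index=barcodes),
        sample_depth=pd.Series(depth_mult, index=list(meta["sample_id"])),
        seed=seed,
    )
    return truth, counts


def _unique_barcodes(rng, n: int, min_separation: int = 0) -> list:
    """Random distinct 24-mers, optionally pairwise >= min_separation edits."""
    if min_separation > 0 and n > 20000:
        raise ValueError(
            f"infeasible barcode-separation request: {n} barcodes at pairwise "
            f"distance >= {min_separation} is not supported"
        )
    out: list = []
    seen = set()
    if min_separation <= 1:
        # distinctness only: draw in vectorized batches
        while len(out) < n:
            need = n - len(out)
            block = rng.integers(0, 4, size=(int(need * 1.05) + 8, BARCODE_LEN))
            letters = np.array(list(BASES))
            for row in letters[block]:
                bc = "".join(row)
                if bc not in seen:
                    seen.add(bc)
                    out.append(bc)
                    if len(out) == n:
                        break
        return out
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise ValueError("infeasible barcode-separation request")
        bc = _rand_seq(rng, BARCODE_LEN)
        if bc in seen:
            continue
        if any(levenshtein(bc, other, k=min_separation - 1) >= 0 for other in out):
            continue
        seen.add(bc)
        out.append(bc)
    return out


# ---------------------------------------------------------------------------
# Read-level simulation


@dataclass
class SimulatedScreen:
    truth: GroundTruth
    counts: CountMatrix
    dictionary_pairs: dict  # pool_id -> list[(unit_read, barcode_read)]
    sample_reads: dict  # sample_id -> list[str]
    spike_in_refs: list
    pool_to_minprom: dict
    unit_cores: dict
    layout: dict


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = BASES[(BASES.index(arr[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def simulate_screen(
    units: list[TreUnit],
    design_config: DesignConfig,
    config: SimulationConfig,
    conditions=("ctrl", "treat"),
    seed: int = 0,
    out_dir=None,
    min_promoters=MIN_PROMOTERS,
) -> SimulatedScreen:
    """Simulate a full screen down to reads for a designed unit library.

    Every unit is crossed with each minimal promoter (one barcoding pool per
    minimal promoter).  Emits dictionary read pairs (unit core + barcode),
    per-sample barcode reads with substitution errors, and spike-in reads;
    serializes everything under ``out_dir`` when given.
    """
    rng = np.random.default_rng([seed, 303])
    cores = {u.unit_id: unit_core(u, design_config) for u in units}
    pool_to_minprom = {f"pool_{mp}": mp for mp in min_promoters}
    promoter_ids = [
        f"{u.unit_id}|{mp}" for u in units for mp in min_promoters
    ]
    n_prom = len(promoter_ids)
    n_bc = _barcode_counts(rng, n_prom, config)
    barcodes = _unique_barcodes(
        rng, int(n_bc.sum()), min_separation=config.barcode_min_separation
    )
    bc_to_prom, props = {}, np.empty(len(barcodes))
    pos = 0
    for pid, k in zip(promoter_ids, n_bc):
        p = rng.dirichlet(np.ones(k))
        props[pos:pos + k] = p
        for j in range(k):
            bc_to_prom[barcodes[pos + j]] = pid
        pos += k
    rates, effects = _draw_promoter_params(rng, promoter_ids, config, conditions)
    meta = _sample_meta(config, conditions)
    depth_mult = np.exp(rng.normal(0.0, config.sample_depth_sigma, size=len(meta)))
    prom_idx = {pid: i for i, pid in enumerate(promoter_ids)}
    prom_per_bc = np.array([prom_idx[bc_to_prom[bc]] for bc in barcodes])
    scale_bc = props * n_bc[prom_per_bc]
    rate_bc = rates.to_numpy()[prom_per_bc]

    values = np.empty((len(barcodes), len(meta)), dtype=np.int64)
    for s, row in enumerate(meta.itertuples(index=False)):
        if row.material == "DNA":
            mean = config.dna_depth * scale_bc * depth_mult[s]
        else:
            eff = effects[row.condition].to_numpy()[prom_per_bc]
            mean = config.rna_depth * scale_bc * rate_bc * eff * depth_mult[s]
        values[:, s] = _nb_draw(rng, mean, config.nb_dispersion)
    counts = CountMatrix(
        values=pd.DataFrame(values, index=barcodes, columns=meta["sample_id"]),
        meta=meta,
    )

    # dictionary read pairs, grouped by minimal-promoter pool
    unit_of_prom = {pid: pid.split("|")[0] for pid in promoter_ids}
    dictionary_pairs = {pool: [] for pool in pool_to_minprom}
    for bc in barcodes:
        pid = bc_to_prom[bc]
        mp = pid.split("|")[1]
        pool = f"pool_{mp}"
        core = cores[unit_of_prom[pid]]
        bc_read = bc + _rand_seq(rng, config.read_tail_length)
        for _ in range(config.dictionary_reads_per_barcode):
            dictionary_pairs[pool].append(
                (
                    _mutate(rng, core, config.dictionary_error_rate),
                    _mutate(rng, bc_read, config.dictionary_error_rate),
                )
            )

    # spike-in references, distinct from all barcodes in their 24-nt prefix
    spike_refs = []
    while len(spike_refs) < config.n_spike_refs:
        ref = _rand_seq(rng, BARCODE_LEN + config.read_tail_length)
        if ref[:BARCODE_LEN] not in bc_to_prom:
            spike_refs.append(ref)

    # per-sample reads: each barcode contributes its count, plus spike-ins
    eps = config.substitution_error_rate
    sample_reads = {}
    for s, sample_id in enumerate(meta["sample_id"]):
        reads = []
        col = values[:, s]
        for bc, c in zip(barcodes, col):
            if c == 0:
                continue
            tail = _rand_seq(rng, config.read_tail_length)
            for _ in range(int(c)):
                reads.append(_mutate(rng, bc + tail, eps))
        f = config.spike_in_fraction
        n_spike = int(round(len(reads) * f / (1.0 - f))) if f > 0 else 0
        for _ in range(n_spike):
            ref = spike_refs[int(rng.integers(0, len(spike_refs)))]
            reads.append(ref)
        order = rng.permutation(len(reads))
        sample_reads[sample_id] = [reads[i] for i in order]

    layout = {
        "seed": seed,
        "barcode_start": 0,
        "barcode_length": BARCODE_LEN,
        "unit_read": "full_core",
        "read_length": BARCODE_LEN + config.read_tail_length,
        "pools": pool_to_minprom,
    }
    truth = GroundTruth(
        barcode_to_promoter=bc_to_prom,
        baseline_rate=rates,
        effects=effects,
        copy_proportions=pd.Series(props, index=barcodes),
        sample_depth=pd.Series(depth_mult, index=list(meta["sample_id"])),
        seed=seed,
    )
    screen = SimulatedScreen(
        truth=truth,
        counts=counts,
        dictionary_pairs=dictionary_pairs,
        sample_reads=sample_reads,
        spike_in_refs=spike_refs,
        pool_to_minprom=pool_to_minprom,
        unit_cores=cores,
        layout=layout,
    )
    if out_dir is not None:
        write_screen(screen, units, config, out_dir)
    return screen


# ---------------------------------------------------------------------------
# Serialization


def _write_fastq(path, reads, seed: int) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read_{i} seed={seed}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_screen(screen: SimulatedScreen, units, config: SimulationConfig, out_dir):
    """Serialize a simulated screen as FASTA/FASTQ/TSV/JSON text files."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = screen.truth.seed
    with open(out / "units.fasta", "w") as fh:
        for u in units:
            fh.write(f">{u.unit_id}\n{u.oligo}\n")
    with open(out / "unit_cores.fasta", "w") as fh:
        for unit_id, core in screen.unit_cores.items():
            fh.write(f">{unit_id}\n{core}\n")
    for pool, pairs in screen.dictionary_pairs.items():
        _write_fastq(out / f"dict_{pool}_R1.fastq", [p[0] for p in pairs], seed)
        _write_fastq(out / f"dict_{pool}_R2.fastq", [p[1] for p in pairs], seed)
    for sample_id, reads in screen.sample_reads.items():
        _write_fastq(out / f"{sample_id}.fastq", reads, seed)
    with open(out / "spike_ins.fasta", "w") as fh:
        for i, ref in enumerate(screen.spike_in_refs):
            fh.write(f">spike_{i}\n{ref}\n")
    header = f"# seed={seed}\n"
    with open(out / "counts.tsv", "w") as fh:
        fh.write(header)
        screen.counts.values.to_csv(fh, sep="\t", index_label="barcode")
    with open(out / "sample_meta.tsv", "w") as fh:
        fh.write(header)
        screen.counts.meta.to_csv(fh, sep="\t", index=False)
    with open(out / "truth_dictionary.tsv", "w") as fh:
        fh.write(header)
        pd.DataFrame(
            sorted(screen.truth.barcode_to_promoter.items()),
            columns=["barcode", "promoter_id"],
        ).to_csv(fh, sep="\t", index=False)
    truth_json = {
        "seed": seed,
        "baseline_rate": screen.truth.baseline_rate.to_dict(),
        "effects": screen.truth.effects.to_dict(),
        "config": asdict(config),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, default=list)
    with open(out / "layout.json", "w") as fh:
        json.dump(screen.layout, fh, indent=1)


def read_simulated_counts(counts_path, meta_path) -> CountMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, comment="#")
    return CountMatrix(values=values, meta=meta)
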