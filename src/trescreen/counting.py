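"""Barcode extraction, sphere clustering and cluster retention.

Per-sample barcode counts come from the first 24 nt of each read.  Counts
are collapsed by greedy sphere clustering at Levenshtein radius 1 (the most
abundant unassigned barcode absorbs every unassigned barcode within the
radius), then clusters are screened against the barcode dictionary: a
cluster is kept only when its centroid is a dictionary barcode and every
other dictionary member of the cluster maps to the same promoter.  Reads of
a retained cluster are summed and assigned to the centroid.  Spike-in reads
are tallied separately as a per-sample quality signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import BARCODE_LEN, BarcodeDictionary, levenshtein
from .motifs import BASES


class FastqError(ValueError):
    """Malformed FASTQ record."""


@dataclass
class RawBarcodeTally:
    sample_id: str
    counts: dict  # 24-mer -> read count
    dropped_reads: int = 0
    spike_in_counts: dict = field(default_factory=dict)

    @property
    def tre_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def tre_read_fraction(self) -> float:
        total = self.tre_reads + sum(self.spike_in_counts.values()) + self.dropped_reads
        return self.tre_reads / total if total else 0.0


@dataclass
class BarcodeCluster:
    centroid: str
    members: dict  # 24-mer -> count, includes the centroid

    @property
    def total(self) -> int:
        return sum(self.members.values())


@dataclass
class SampleCounts:
    sample_id: str
    accepted: dict  # dictionary barcode -> collapsed count
    spike_in_counts: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)


def extract_barcodes(
    reads,
    spike_in_refs=(),
    sample_id: str = "sample",
    barcode_len: int = BARCODE_LEN,
) -> RawBarcodeTally:
    """Tally the first ``barcode_len`` nt of each read.

    ``reads`` is an iterable of sequence strings (see :func:`read_fastq_seqs`).
    Reads whose prefix exactly matches a spike-in reference prefix are
    tallied separately; reads shorter than the barcode or with non-ACGT in
    the prefix are counted as dropped.
    """
    spike_prefix = {}
    for i, ref in enumerate(spike_in_refs):
        if len(ref) < barcode_len:
            raise ValueError(f"spike-in reference {i} shorter than {barcode_len} nt")
        spike_prefix[ref[:barcode_len].upper()] = f"spike_{i}"
    counts: dict = {}
    spikes: dict = {sid: 0 for sid in spike_prefix.values()}
    dropped = 0
    for read in reads:
        prefix = read[:barcode_len].upper()
        sid = spike_prefix.get(prefix)
        if sid is not None:
            spikes[sid] += 1
            continue
        if len(prefix) < barcode_len or any(c not in BASES for c in prefix):
            dropped += 1
            continue
        counts[prefix] = counts.get(prefix, 0) + 1
    return RawBarcodeTally(
        sample_id=sample_id, counts=counts, dropped_reads=dropped,
        spike_in_counts=spikes,
    )


def _neighbor_candidates(barcodes: list) -> dict:
    """Candidate distance<=1 neighbor pairs via half-string pigeonholing.

    For equal-length strings a single edit is a substitution, so one half is
    always preserved exactly; strings sharing either half are candidates.
    Returns {barcode: set of candidate neighbors}.
    """
    buckets: dict = {}
    n = len(barcodes[0]) // 2
    for bc in barcodes:
        buckets.setdefault(("L", bc[:n]), []).append(bc)
        buckets.setdefault(("R", bc[n:]), []).append(bc)
    cand = {bc: set() for bc in barcodes}
    for members in buckets.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                cand[a].add(b)
                cand[b].add(a)
    return cand


def sphere_cluster(tally: RawBarcodeTally, radius: int = 1) -> list:
    """Greedy sphere clustering of a barcode tally at a Levenshtein radius.

    Repeatedly selects the highest-count unassigned barcode (ties broken
    lexicographically) as a centroid and absorbs all unassigned barcodes
    within the radius.  The result partitions the input barcodes and is
    deterministic.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    counts = tally.counts
    order = sorted(counts, key=lambda bc: (-counts[bc], bc))
    if not order:
        return []
    if radius == 0:
        return [BarcodeCluster(bc, {bc: counts[bc]}) for bc in order]
    lengths = {len(bc) for bc in counts}
    use_buckets = radius == 1 and len(lengths) == 1
    cand = _neighbor_candidates(order) if use_buckets else None
    assigned: set = set()
    clusters = []
    for centroid in order:
        if centroid in assigned:
            continue
        assigned.add(centroid)
        members = {centroid: counts[centroid]}
        pool = cand[centroid] if use_buckets else counts
        for bc in sorted(pool):
            if bc in assigned:
                continue
            if levenshtein(centroid, bc, k=radius) >= 0:
                members[bc] = counts[bc]
                assigned.add(bc)
        clusters.append(BarcodeCluster(centroid, members))
    return clusters


def retain_clusters(
    clusters,
    dictionary: BarcodeDictionary,
    sample_id: str = "sample",
    spike_in_counts: dict | None = None,
    tre_read_fraction: float | None = None,
) -> SampleCounts:
    """Apply the dictionary-based cluster retention rules.

    A cluster is retained iff its centroid is in the dictionary and every
    non-centroid member that is also in the dictionary maps to the same
    promoter as the centroid; its summed reads are assigned to the centroid.
    """
    accepted: dict = {}
    discarded = 0
    for cluster in clusters:
        target = dictionary.promoter_of(cluster.centroid)
        if target is None:
            discarded += 1
            continue
        ok = all(
            dictionary.promoter_of(bc) in (None, target)
            for bc in cluster.members
            if bc != cluster.centroid
        )
        if not ok:
            discarded += 1
            continue
        accepted[cluster.centroid] = accepted.get(cluster.centroid, 0) + cluster.total
    qc = {"clusters_discarded": discarded, "clusters_retained": len(accepted)}
    if tre_read_fraction is not None:
        qc["tre_read_fraction"] = tre_read_fraction
    return SampleCounts(
        sample_id=sample_id,
        accepted=accepted,
        spike_in_counts=dict(spike_in_counts or {}),
        qc=qc,
    )


def count_sample(
    reads,
    dictionary: BarcodeDictionary,
    spike_in_refs=(),
    sample_id: str = "sample",
    radius: int = 1,
) -> SampleCounts:
    """Full per-sample pipeline: extract, cluster, retain."""
    tally = extract_barcodes(reads, spike_in_refs, sample_id=sample_id)
    clusters = sphere_cluster(tally, radius=radius)
    return retain_clusters(
        clusters,
        dictionary,
        sample_id=sample_id,
        spike_in_counts=tally.spike_in_counts,
        tre_read_fraction=tally.tre_read_fraction,
    )


def qc_flag(
    sample: SampleCounts,
    cohort_fractions,
    relative: float = 0.5,
    floor: float = 0.5,
) -> SampleCounts:
    """Flag a sample with a disproportionately low TRE-read fraction.

    The default threshold is ``max(relative x cohort median fraction,
    floor)``; a single-sample cohort is effectively compared to the floor
    alone.  Flag-only: the sample is never dropped automatically.
    """
    fractions = list(cohort_fractions)
    if not fractions:
        raise ValueError("cohort must contain at least one sample")
    threshold = max(relative * float(np.median(fractions)), floor)
    frac = sample.qc.get("tre_read_fraction")
    if frac is None:
        raise ValueError(f"sample {sample.sample_id} has no tre_read_fraction")
    sample.qc["flag_threshold"] = threshold
    sample.qc["flagged"] = bool(frac < threshold)
    return sample


# ---------------------------------------------------------------------------
# I/O


def read_fastq_seqs(path):
    """Yield read sequences from a FASTQ file, validating record structure."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise FastqError(f"malformed FASTQ record at index {idx} in {path}")
            seq, qual = seq.strip(), qual.strip()
            if len(seq) != len(qual):
                raise FastqError(f"malformed FASTQ record at index {idx} in {path}")
            yield seq
            idx += 1


def write_counts_tsv(sample: SampleCounts, path) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(sample.accepted.items()), columns=["barcode", "count"]
    ).to_csv(path, sep="\t", index=False)
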