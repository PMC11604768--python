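"""Barcode-to-promoter dictionary construction.

Paired dictionary sequencing reads one end across the TRE-unit core and the
other across the 24-nt barcode.  A pair is kept when the observed unit read
is within Levenshtein distance 2 of exactly one expected unit; a barcode
seen with more than one promoter (different units, or the same unit in pools
carrying different minimal promoters) is discarded entirely, making the
final barcode -> promoter map injective as a function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .motifs import BASES

BARCODE_LEN = 24


@dataclass
class DictionaryReadPair:
    unit_read: str
    barcode_read: str
    pool_id: str


@dataclass
class DictionaryEntry:
    barcode: str
    promoter_id: str
    unit_id: str
    min_promoter: str
    support: int


@dataclass
class BarcodeDictionary:
    """Injective map from 24-nt barcodes to promoter identifiers."""

    entries: dict  # barcode -> DictionaryEntry
    qc: dict = field(default_factory=dict)

    def promoter_of(self, barcode: str):
        e = self.entries.get(barcode)
        return e.promoter_id if e else None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.entries


def levenshtein(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance via edlib; -1 if it exceeds the bound k."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def match_unit(observed: str, expected_units: dict, max_dist: int = 2):
    """Match an observed unit read against expected unit core sequences.

    ``expected_units`` maps unit_id -> core sequence (pairwise distinct).
    Returns the unit_id of the unique nearest unit within ``max_dist``
    Levenshtein edits, or None when no unit qualifies or two tie at the
    minimal distance (ambiguous reads are data, not errors).
    """
    best_id, best_d, tie = None, max_dist + 1, False
    for unit_id, core in expected_units.items():
        d = levenshtein(observed, core, k=max_dist)
        if d < 0:
            continue
        if d < best_d:
            best_id, best_d, tie = unit_id, d, False
        elif d == best_d:
            tie = True
    if best_id is None or tie:
        return None
    return best_id


def build_dictionary(
    pairs,
    expected_units: dict,
    pool_to_minprom: dict,
    max_dist: int = 2,
    barcode_len: int = BARCODE_LEN,
) -> BarcodeDictionary:
    """Build the barcode dictionary from a stream of DictionaryReadPair.

    The barcode is the first ``barcode_len`` nt of the barcode read.  Pairs
    whose unit read matches no unique expected unit are dropped; barcodes
    observed with two or more distinct promoters are removed entirely.
    """
    support: dict = {}  # barcode -> {promoter_id: (unit_id, minprom, count)}
    qc = {"pairs": 0, "bad_barcode": 0, "unmatched_unit": 0, "multi_mapped": 0}
    for pair in pairs:
        qc["pairs"] += 1
        bc = pair.barcode_read[:barcode_len]
        if len(bc) < barcode_len or any(c not in BASES for c in bc):
            qc["bad_barcode"] += 1
            continue
        unit_id = match_unit(pair.unit_read, expected_units, max_dist)
        if unit_id is None:
            qc["unmatched_unit"] += 1
            continue
        minprom = pool_to_minprom[pair.pool_id]
        promoter_id = f"{unit_id}|{minprom}"
        by_prom = support.setdefault(bc, {})
        uid, mp, n = by_prom.get(promoter_id, (unit_id, minprom, 0))
        by_prom[promoter_id] = (uid, mp, n + 1)
    entries = {}
    for bc, by_prom in support.items():
        if len(by_prom) > 1:
            qc["multi_mapped"] += 1
            continue
        promoter_id, (unit_id, minprom, n) = next(iter(by_prom.items()))
        entries[bc] = DictionaryEntry(bc, promoter_id, unit_id, minprom, n)
    return BarcodeDictionary(entries=entries, qc=qc)


# ---------------------------------------------------------------------------
# I/O


def read_fastq_pairs(r1_path, r2_path, pool_id: str):
    """Read paired FASTQs as DictionaryReadPairs (R1 = unit, R2 = barcode)."""
    from Bio import SeqIO

    pairs = []
    r1 = SeqIO.parse(str(r1_path), "fastq")
    r2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(r1, r2, strict=True):
        pairs.append(
            DictionaryReadPair(
                unit_read=str(rec1.seq).upper(),
                barcode_read=str(rec2.seq).upper(),
                pool_id=pool_id,
            )
        )
    return pairs


def write_dictionary_tsv(dictionary: BarcodeDictionary, path) -> None:
    rows = dictionary.entries.values()
    pd.DataFrame(
        {
            "barcode": [e.barcode for e in rows],
            "promoter_id": [e.promoter_id for e in rows],
            "unit_id": [e.unit_id for e in rows],
            "min_promoter": [e.min_promoter for e in rows],
            "support": [e.support for e in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def read_dictionary_tsv(path) -> BarcodeDictionary:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "support": int})
    entries = {
        r.barcode: DictionaryEntry(
            r.barcode, r.promoter_id, r.unit_id, r.min_promoter, int(r.support)
        )
        for r in df.itertuples(index=False)
    }
    return BarcodeDictionary(entries=entries)
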