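"""Synthetic-promoter (TRE unit) design with helical phasing.

A TRE unit is a 160-nt oligo carrying four copies of one binding motif,
separated by random-nucleotide spacers whose lengths are chosen so adjacent
copies sit on opposite faces of the B-DNA helix (half-integer turns apart,
period 10.5 bp/turn by default), followed by a rotation segment that turns
the whole motif block relative to the downstream minimal promoter, a 3'
filler that pads the oligo to its fixed synthesis length, and fixed flanks
carrying the cloning sites (MluI/SpeI) and primer landing sequences.

Each experimental motif yields six configurations (2 spacer sets x 3
rotations); units are crossed with three minimal promoters (minTK, minProm,
minCMV) to form the synthetic-promoter library.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import BASES, BindingMotif

MIN_PROMOTERS = ("minTK", "minProm", "minCMV")

# Fixed default flanks: an 18-nt primer site plus the MluI (5') / SpeI (3')
# cloning sites.  The two bases adjoining the variable insert ("CC" / "GG")
# are chosen so that no forbidden recognition site can span a flank/insert
# junction, whatever the insert starts or ends with.
DEFAULT_FLANK_5P = "CAGTCAGGTGCAGACTCA" + "ACGCGT" + "CC"
DEFAULT_FLANK_3P = "GG" + "ACTAGT" + "TGACCTCAGTGACGATCA"

DEFAULT_FORBIDDEN = ("ACGCGT", "ACTAGT", "GGTACC", "TCTAGA")  # MluI SpeI KpnI XbaI


class DesignError(ValueError):
    """Raised when a unit cannot be designed under the configuration."""


@dataclass
class DesignConfig:
    """Parameters of the TRE-unit design.

    ``spacer_sets`` holds one rng seed per spacer set; with the default two
    sets and three rotations every experimental motif yields six
    configurations.  ``rotations`` are the lengths (nt) of the random segment
    inserted between the final motif copy and the 3' filler; 4 and 8 nt give
    roughly one-third and two-thirds of a helical turn.
    """

    helical_period: float = 10.5
    oligo_length: int = 160
    copies: int = 4
    spacer_sets: tuple = (11, 23)
    rotations: tuple = (0, 4, 8)
    forbidden_sites: tuple = DEFAULT_FORBIDDEN
    flank_5p: str = DEFAULT_FLANK_5P
    flank_3p: str = DEFAULT_FLANK_3P
    max_redraws: int = 1000
    control_spacer_set: int = 0
    control_rotation: int = 0

    def __post_init__(self) -> None:
        for name, flank in (("flank_5p", self.flank_5p), ("flank_3p", self.flank_3p)):
            if any(c not in BASES for c in flank):
                raise DesignError(f"{name} is not plain ACGT")
        # designed (allowed) site positions, in flank-local coordinates
        self.designed_sites_5p = _scan_sites(self.flank_5p, self.forbidden_sites)
        self.designed_sites_3p = _scan_sites(self.flank_3p, self.forbidden_sites)

    def allowed_site_positions(self, oligo_length: int) -> set:
        """Start positions where a forbidden site is designed to occur."""
        off3 = oligo_length - len(self.flank_3p)
        return {start for start, _ in self.designed_sites_5p} | {
            off3 + start for start, _ in self.designed_sites_3p
        }


@dataclass
class TreUnit:
    unit_id: str
    motif_id: str
    spacer_set: int
    rotation: int
    oligo: str
    layout: list  # (segment name, start, end), 0-based half-open
    provenance: str = "experimental"

    def segment(self, name: str) -> list:
        return [(s, e) for n, s, e in self.layout if n == name]


@dataclass
class SyntheticPromoter:
    promoter_id: str
    unit_id: str
    min_promoter: str


def _scan_sites(seq: str, sites) -> list:
    """All (start, site) occurrences of any site in seq."""
    hits = []
    for site in sites:
        start = seq.find(site)
        while start != -1:
            hits.append((start, site))
            start = seq.find(site, start + 1)
    return sorted(hits)


def _phase_deviation(length: float, period: float) -> float:
    """Circular deviation of `length` from a half-integer number of turns."""
    k = np.floor(length / period - 0.5)
    cands = [abs(length - period * (kk + 0.5)) for kk in (k, k + 1) if kk >= 0]
    cands.append(abs(length - period * 0.5))
    return float(min(cands))


def phasing_spacer_length(motif_length: int, config: DesignConfig | None = None) -> int:
    """Smallest spacer s placing adjacent motif copies on opposite helix faces.

    Minimizes, over integers s >= 0, the circular deviation of
    ``motif_length + s`` from a half-integer number of helical turns; the
    smallest s attaining the minimum is returned (for period 10.5 the
    attainable minimum with integer lengths is 0.25 bp).
    """
    if motif_length < 1:
        raise DesignError("motif_length must be >= 1")
    config = config or DesignConfig()
    return _spacer_candidates(motif_length, config)[0]


def _spacer_candidates(motif_length: int, config: DesignConfig) -> list:
    """Spacer lengths attaining the minimal phase deviation, ascending."""
    period = config.helical_period
    smax = int(np.ceil(period)) * 3
    devs = [
        (_phase_deviation(motif_length + s, period), s) for s in range(smax + 1)
    ]
    dmin = min(d for d, _ in devs)
    return [s for d, s in devs if d <= dmin + 1e-9]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def generate_tre_unit(
    motif: BindingMotif,
    spacer_set: int,
    rotation: int,
    config: DesignConfig | None = None,
    rng_seed: int = 0,
) -> TreUnit:
    """Design one TRE unit for a motif in one configuration.

    The oligo is ``flank_5p + (motif + spacer) x 3 + motif + rotation segment
    + 3' filler + flank_3p`` with total length ``config.oligo_length``.  All
    random segments come from an rng seeded deterministically by (global
    seed, spacer-set seed, rotation, motif id).  Any draw creating a
    forbidden restriction site outside the designed flank positions is
    redrawn; if the site is unremovable at the phase-optimal spacer length
    (e.g. a zero-length spacer joins two motif copies into a site) the next
    spacer length with equal phase deviation is tried before giving up.
    """
    config = config or DesignConfig()
    if not 0 <= spacer_set < len(config.spacer_sets):
        raise DesignError(f"spacer_set index {spacer_set} out of range")
    L = len(motif.sequence)
    motif_hash = zlib.crc32(motif.motif_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(
        [rng_seed, config.spacer_sets[spacer_set], rotation, motif_hash]
    )
    fixed = len(config.flank_5p) + len(config.flank_3p) + config.copies * L + rotation
    candidates = [
        s for s in _spacer_candidates(L, config)
        if fixed + (config.copies - 1) * s <= config.oligo_length
    ]
    if not candidates:
        raise DesignError(
            f"unit too long: motif {motif.motif_id} ({L} nt) does not fit in "
            f"{config.oligo_length} nt at any phase-optimal spacer length"
        )
    allowed = config.allowed_site_positions(config.oligo_length)
    for s in candidates:
        filler_len = config.oligo_length - fixed - (config.copies - 1) * s
        for _ in range(config.max_redraws):
            spacers = [_rand_seq(rng, s) for _ in range(config.copies - 1)]
            rot_seg = _rand_seq(rng, rotation)
            filler = _rand_seq(rng, filler_len)
            parts = [("flank_5p", config.flank_5p)]
            for i in range(config.copies):
                parts.append((f"motif_{i + 1}", motif.sequence))
                if i < config.copies - 1:
                    parts.append((f"spacer_{i + 1}", spacers[i]))
            parts.append(("rotation", rot_seg))
            parts.append(("filler_3p", filler))
            parts.append(("flank_3p", config.flank_3p))
            oligo = "".join(seq for _, seq in parts)
            hits = _scan_sites(oligo, config.forbidden_sites)
            if all(start in allowed for start, _ in hits):
                layout, pos = [], 0
                for name, seq in parts:
                    layout.append((name, pos, pos + len(seq)))
                    pos += len(seq)
                return TreUnit(
                    unit_id=f"{motif.motif_id}_s{spacer_set}_r{rotation}",
                    motif_id=motif.motif_id,
                    spacer_set=spacer_set,
                    rotation=rotation,
                    oligo=oligo,
                    layout=layout,
                    provenance=motif.provenance,
                )
    raise DesignError(
        f"redraw budget exhausted for motif {motif.motif_id} "
        f"(spacer_set {spacer_set}, rotation {rotation}); a forbidden site may "
        "be unremovable"
    )


def validate_unit(unit: TreUnit, motif: BindingMotif, config: DesignConfig) -> None:
    """Check the structural invariants of a designed unit (raises on failure)."""
    if len(unit.oligo) != config.oligo_length:
        raise DesignError(f"{unit.unit_id}: length {len(unit.oligo)}")
    rebuilt = "".join(unit.oligo[s:e] for _, s, e in unit.layout)
    if rebuilt != unit.oligo or unit.layout[0][1] != 0 or unit.layout[-1][2] != len(unit.oligo):
        raise DesignError(f"{unit.unit_id}: layout does not tile the oligo")
    motif_spans = [(s, e) for n, s, e in unit.layout if n.startswith("motif_")]
    if len(motif_spans) != config.copies:
        raise DesignError(f"{unit.unit_id}: expected {config.copies} motif segments")
    for s, e in motif_spans:
        if unit.oligo[s:e] != motif.sequence:
            raise DesignError(f"{unit.unit_id}: motif mismatch at {s}:{e}")
    for (s1, _), (s2, _) in zip(motif_spans, motif_spans[1:]):
        dev = _phase_deviation(s2 - s1, config.helical_period)
        if dev > 0.25 + 1e-9:
            raise DesignError(
                f"{unit.unit_id}: phase deviation {dev:.3f} bp between copies"
            )
    allowed = config.allowed_site_positions(len(unit.oligo))
    for start, site in _scan_sites(unit.oligo, config.forbidden_sites):
        if start not in allowed:
            raise DesignError(
                f"{unit.unit_id}: forbidden site {site} at position {start}"
            )


def generate_library(
    catalog: list[BindingMotif],
    commercial_units: list | None = None,
    config: DesignConfig | None = None,
    rng_seed: int = 0,
) -> tuple[list[TreUnit], list[SyntheticPromoter], pd.DataFrame]:
    """Design the full unit library and cross it with the minimal promoters.

    Experimental motifs get one unit per (spacer set x rotation); negative
    controls get a single configuration; commercial units (``(unit_id,
    oligo)`` pairs) pass through unmodified and may exceed the synthesis
    length.  Returns (units, promoters, design manifest).
    """
    config = config or DesignConfig()
    units: list[TreUnit] = []
    for motif in catalog:
        if motif.provenance == "experimental":
            combos = [
                (i, r) for i in range(len(config.spacer_sets)) for r in config.rotations
            ]
        else:
            combos = [(config.control_spacer_set, config.control_rotation)]
        for i, r in combos:
            units.append(generate_tre_unit(motif, i, r, config, rng_seed))
    for unit_id, oligo in commercial_units or []:
        units.append(
            TreUnit(
                unit_id=unit_id,
                motif_id=unit_id,
                spacer_set=-1,
                rotation=0,
                oligo=oligo,
                layout=[("commercial", 0, len(oligo))],
                provenance="commercial",
            )
        )
    promoters = [
        SyntheticPromoter(f"{u.unit_id}|{mp}", u.unit_id, mp)
        for u in units
        for mp in MIN_PROMOTERS
    ]
    manifest = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "motif_id": [u.motif_id for u in units],
            "provenance": [u.provenance for u in units],
            "spacer_set": [u.spacer_set for u in units],
            "rotation": [u.rotation for u in units],
            "oligo_length": [len(u.oligo) for u in units],
            "motif_positions": [
                ";".join(f"{s}-{e}" for n, s, e in u.layout if n.startswith("motif_"))
                for u in units
            ],
        }
    )
    return units, promoters, manifest


# ---------------------------------------------------------------------------
# I/O


def unit_core(unit: TreUnit, config: DesignConfig) -> str:
    """The sequenced core of a unit: the oligo between the fixed flanks."""
    if unit.provenance == "commercial":
        return unit.oligo
    start = len(config.flank_5p)
    end = len(unit.oligo) - len(config.flank_3p)
    return unit.oligo[start:end]


def write_units_fasta(units: list[TreUnit], path) -> None:
    with open(path, "w") as fh:
        for u in units:
            fh.write(f">{u.unit_id}\n{u.oligo}\n")


def read_units_fasta(path) -> dict:
    """Read unit oligos as an ordered {unit_id: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_promoters_tsv(promoters: list[SyntheticPromoter], path) -> None:
    pd.DataFrame(
        {
            "promoter_id": [p.promoter_id for p in promoters],
            "unit_id": [p.unit_id for p in promoters],
            "min_promoter": [p.min_promoter for p in promoters],
        }
    ).to_csv(path, sep="\t", index=False)
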