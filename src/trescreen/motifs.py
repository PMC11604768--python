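"""Transcription-factor binding-motif catalog construction.

Turns position-weight-matrix (PWM) seed sequences — IUPAC strings with an
accompanying L x 4 weight matrix — into a deduplicated catalog of plain-ACGT
binding motifs.  The procedure is: trim fully degenerate positions (the code
``N`` specifically) from both ends, replace every remaining degenerate
position with the predominant base of its PWM row, then drop any motif whose
entire sequence is contained within another motif's sequence.  Scrambled
copies of experimental motifs serve as negative controls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = "ACGT"

#: IUPAC nucleotide codes mapped to the set of bases they permit.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class MotifError(ValueError):
    """Raised for invalid seeds or unresolvable motif operations."""


@dataclass
class PwmSeed:
    """A PWM seed sequence with per-position base weights.

    Parameters
    ----------
    tf_name : str
        Transcription-factor label.
    species : str
        One of ``human``, ``mouse``, ``synthetic``.
    seed : str
        IUPAC string (A, C, G, T plus degenerate codes incl. N), length >= 4.
    pwm : ndarray of shape (len(seed), 4)
        Nonnegative weights, columns ordered A, C, G, T.
    """

    tf_name: str
    species: str
    seed: str
    pwm: np.ndarray

    def __post_init__(self) -> None:
        self.seed = self.seed.upper()
        self.pwm = np.asarray(self.pwm, dtype=float)
        if len(self.seed) < 4:
            raise MotifError(f"seed {self.seed!r} shorter than 4 nt")
        bad = [c for c in self.seed if c not in IUPAC]
        if bad:
            raise MotifError(f"seed {self.seed!r} has non-IUPAC codes {bad}")
        if self.pwm.shape != (len(self.seed), 4):
            raise MotifError(
                f"pwm shape {self.pwm.shape} does not match seed length "
                f"{len(self.seed)}"
            )
        if (self.pwm < 0).any():
            raise MotifError("pwm weights must be nonnegative")
        if not (self.pwm.sum(axis=1) > 0).all():
            raise MotifError("every pwm row needs at least one positive entry")


@dataclass
class BindingMotif:
    """A plain-ACGT binding motif with provenance.

    provenance is one of ``experimental``, ``commercial``,
    ``negative_control``.
    """

    motif_id: str
    tf_name: str
    sequence: str
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence or any(c not in BASES for c in self.sequence):
            raise MotifError(
                f"motif {self.motif_id}: sequence {self.sequence!r} is not "
                "plain ACGT"
            )
        if self.provenance not in ("experimental", "commercial", "negative_control"):
            raise MotifError(f"unknown provenance {self.provenance!r}")


def resolve_seed(seed: PwmSeed, motif_id: str | None = None) -> BindingMotif:
    """Resolve an IUPAC seed into a plain-ACGT motif.

    Fully degenerate positions (code ``N``) are trimmed from the 5' and 3'
    ends; every remaining degenerate position is replaced by the base with
    maximal PWM weight there (ties broken alphabetically).  Internal Ns are
    replaced, not removed.

    Raises
    ------
    MotifError
        If the seed is all N ("empty motif") or a degenerate position has an
        all-zero PWM row.
    """
    s = seed.seed
    start = 0
    while start < len(s) and s[start] == "N":
        start += 1
    end = len(s)
    while end > start and s[end - 1] == "N":
        end -= 1
    if start >= end:
        raise MotifError(f"seed {s!r} yields an empty motif (all N)")

    out = []
    for i in range(start, end):
        c = s[i]
        if c in BASES:
            out.append(c)
            continue
        row = seed.pwm[i]
        if row.sum() <= 0:
            raise MotifError(
                f"degenerate position {i} of seed {s!r} has an all-zero pwm row"
            )
        # argmax breaks ties toward the alphabetically first base because
        # columns are ordered A,C,G,T
        out.append(BASES[int(np.argmax(row))])
    return BindingMotif(
        motif_id=motif_id or seed.tf_name,
        tf_name=seed.tf_name,
        sequence="".join(out),
        provenance="experimental",
    )


def deduplicate_motifs(motifs: list[BindingMotif]) -> list[BindingMotif]:
    """Drop every motif whose entire sequence occurs within another motif.

    Containment is checked on the forward strand only, as a contiguous
    substring.  Among exact duplicates the first by input order is kept.
    Output order preserves input order.
    """
    kept = []
    for i, m in enumerate(motifs):
        contained = False
        for j, other in enumerate(motifs):
            if i == j:
                continue
            if m.sequence == other.sequence:
                if j < i:
                    contained = True
                    break
            elif m.sequence in other.sequence:
                contained = True
                break
        if not contained:
            kept.append(m)
    return kept


def scramble_motif(
    motif: BindingMotif, rng_seed: int, max_attempts: int = 100,
    avoid_substrings=(),
) -> BindingMotif | None:
    """Scramble a motif into a negative control of identical base composition.

    Redraws until the permutation differs from the input, is neither a
    substring nor a superstring of it, and contains none of
    ``avoid_substrings`` (e.g. restriction sites the downstream oligo design
    must stay clear of).  Homopolymer motifs cannot differ under permutation;
    they are skipped with a warning and ``None`` returned.
    """
    if motif.provenance != "experimental":
        raise MotifError("only experimental motifs are scrambled into controls")
    seq = motif.sequence
    if len(set(seq)) == 1:
        warnings.warn(
            f"motif {motif.motif_id}: homopolymer {seq!r} cannot be scrambled; "
            "control skipped"
        )
        return None
    rng = np.random.default_rng(rng_seed)
    letters = list(seq)
    for _ in range(max_attempts):
        perm = "".join(rng.permutation(letters))
        if (
            perm != seq and perm not in seq and seq not in perm
            and not any(site in perm for site in avoid_substrings)
        ):
            return BindingMotif(
                motif_id=f"{motif.motif_id}_scr",
                tf_name=motif.tf_name,
                sequence=perm,
                provenance="negative_control",
            )
    raise MotifError(f"could not scramble motif {motif.motif_id} in "
                     f"{max_attempts} attempts")


def build_catalog(
    seeds: list[PwmSeed],
    n_controls: int = 0,
    rng_seed: int = 0,
    avoid_substrings=(),
) -> list[BindingMotif]:
    """Resolve, deduplicate and (optionally) append scrambled controls.

    Controls are scrambles of experimental motifs sampled round-robin across
    the deduplicated catalog, each given a distinct rng stream.
    """
    resolved = [
        resolve_seed(seed, motif_id=f"M{i:04d}_{seed.tf_name}")
        for i, seed in enumerate(seeds)
    ]
    catalog = deduplicate_motifs(resolved)
    controls: list[BindingMotif] = []
    if n_controls > 0:
        if not catalog:
            raise MotifError("cannot draw controls from an empty catalog")
        i = 0
        attempt = 0
        while len(controls) < n_controls:
            src = catalog[i % len(catalog)]
            ctrl = scramble_motif(
                src, rng_seed=rng_seed + attempt, avoid_substrings=avoid_substrings
            )
            attempt += 1
            i += 1
            if ctrl is not None:
                ctrl.motif_id = f"NC{len(controls):04d}_{src.motif_id}"
                controls.append(ctrl)
    return catalog + controls


# ---------------------------------------------------------------------------
# I/O — seeds+PWM TSV and motif-catalog TSV


def read_seeds_tsv(path) -> list[PwmSeed]:
    """Read seeds from a TSV with columns tf_name, species, seed, pwm.

    The pwm column holds a JSON array of L rows x 4 weights (A,C,G,T).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tf_name", "species", "seed", "pwm"}
    missing = required - set(df.columns)
    if missing:
        raise MotifError(f"seed TSV missing columns {sorted(missing)}")
    return [
        PwmSeed(
            tf_name=row.tf_name,
            species=row.species,
            seed=row.seed,
            pwm=np.array(json.loads(row.pwm), dtype=float),
        )
        for row in df.itertuples(index=False)
    ]


def write_seeds_tsv(seeds: list[PwmSeed], path) -> None:
    df = pd.DataFrame(
        {
            "tf_name": [s.tf_name for s in seeds],
            "species": [s.species for s in seeds],
            "seed": [s.seed for s in seeds],
            "pwm": [json.dumps(np.asarray(s.pwm).tolist()) for s in seeds],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_catalog_tsv(motifs: list[BindingMotif], path) -> None:
    pd.DataFrame(
        {
            "motif_id": [m.motif_id for m in motifs],
            "tf_name": [m.tf_name for m in motifs],
            "sequence": [m.sequence for m in motifs],
            "provenance": [m.provenance for m in motifs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> list[BindingMotif]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        BindingMotif(row.motif_id, row.tf_name, row.sequence, row.provenance)
        for row in df.itertuples(index=False)
    ]
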