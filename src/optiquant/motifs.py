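"""NPxY/F motif logic for integrin beta cytoplasmic tails.

Integrin beta cytoplasmic tails carry two short tyrosine/phenylalanine
motifs: a membrane-proximal N-P-x-[Y/F] (the core talin-binding site) and a
membrane-distal N-x-x-[Y/F] (the kindlin-associated site).  This module
scans tail sequences for both classes, applies point mutations such as the
talin-binding-deficient Y783A substitution of human beta-1, and tabulates
motif presence across a panel of tails.

Coordinates are reported in precursor numbering (1-based, counting the
signal peptide), the convention under which the human beta-1 NPIY tyrosine
is residue 783; each :class:`TailSequence` therefore carries the precursor
index of its first residue.

Classification rule: the membrane-proximal motif is the first N-P-x-[Y/F]
occurrence that starts within the membrane-proximal 60% of the tail (in
every documented tail the proximal motif begins near or before the
midpoint, while the distal motif sits close to the C-terminus).  Any
later, non-overlapping N-x-x-[Y/F] occurrence — including NPxY-shaped
ones, like the distal NPKY of human beta-1 — is membrane-distal.  When no
proximal motif exists (e.g. after a Y783A-type mutation), N-x-x-[Y/F]
occurrences in the C-terminal half of the tail are still reported as
membrane-distal; the distal motif is never promoted to proximal.  No
single occurrence is ever reported under both classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidParameterError, MutationMismatchError, SequenceParseError

__all__ = [
    "MEMBRANE_PROXIMAL",
    "MEMBRANE_DISTAL",
    "TailSequence",
    "MotifHit",
    "find_motifs",
    "apply_mutation",
    "motif_presence_table",
    "read_tails_fasta",
    "write_tails_fasta",
    "load_packaged_tails",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
MEMBRANE_PROXIMAL = "membrane_proximal"  # N-P-x-[Y/F]
MEMBRANE_DISTAL = "membrane_distal"  # N-x-x-[Y/F]

# Fraction of the tail (from its membrane-proximal end) within which the
# membrane-proximal motif must begin; the distal motif of every documented
# tail starts well beyond this point.
PROXIMAL_REGION_FRACTION = 0.6

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class TailSequence:
    """An integrin beta cytoplasmic tail with a precursor-numbering offset."""

    name: str
    residues: str
    start_index: int = 1
    species: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceParseError("empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise SequenceParseError(f"invalid residue characters: {sorted(bad)}")
        if self.start_index < 1:
            raise SequenceParseError("start_index must be >= 1 (precursor numbering)")

    def residue_at(self, position: int) -> str:
        """Residue at a precursor position."""
        i = position - self.start_index
        if not 0 <= i < len(self.residues):
            raise InvalidParameterError(
                f"position {position} outside [{self.start_index}, "
                f"{self.start_index + len(self.residues) - 1}]"
            )
        return self.residues[i]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, in precursor coordinates (end = start + 3)."""

    motif_class: str
    start: int
    end: int
    terminal_residue: str
    sequence: str


def _window_matches(quad: str) -> tuple[bool, bool]:
    """(matches N-x-x-[Y/F], matches N-P-x-[Y/F]) for a 4-residue window."""
    loose = quad[0] == "N" and quad[3] in "YF"
    return loose, loose and quad[1] == "P"


def find_motifs(tail: TailSequence) -> list[MotifHit]:
    """Scan a tail for membrane-proximal and membrane-distal motifs."""
    res = tail.residues
    matches: list[tuple[int, bool]] = []  # (0-based start, is NPx[Y/F])
    for i in range(len(res) - 3):
        loose, strict = _window_matches(res[i : i + 4])
        if loose:
            matches.append((i, strict))

    hits: list[MotifHit] = []
    proximal_start: int | None = None
    proximal_limit = PROXIMAL_REGION_FRACTION * len(res)
    for i, strict in matches:
        if strict and i < proximal_limit:
            proximal_start = i
            hits.append(_hit(tail, i, MEMBRANE_PROXIMAL))
            break

    if proximal_start is not None:
        distal_from = proximal_start + 4  # non-overlapping, strictly after
    else:
        distal_from = len(res) // 2  # C-terminal half fallback
    for i, _ in matches:
        if i >= distal_from and i != proximal_start:
            hits.append(_hit(tail, i, MEMBRANE_DISTAL))
    return hits


def _hit(tail: TailSequence, i: int, motif_class: str) -> MotifHit:
    quad = tail.residues[i : i + 4]
    return MotifHit(
        motif_class=motif_class,
        start=tail.start_index + i,
        end=tail.start_index + i + 3,
        terminal_residue=quad[3],
        sequence=quad,
    )


def apply_mutation(tail: TailSequence, spec: str) -> TailSequence:
    """Apply a point mutation given as e.g. ``"Y783A"`` (precursor numbering).

    The stated reference residue must match the sequence at that position;
    a mismatch raises :class:`MutationMismatchError`, guarding against
    numbering-offset mistakes.
    """
    m = _MUTATION_RE.match(spec)
    if not m:
        raise InvalidParameterError(f"malformed mutation spec {spec!r} (expected e.g. Y783A)")
    ref, pos_s, alt = m.group(1), m.group(2), m.group(3)
    if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS:
        raise InvalidParameterError(f"mutation spec {spec!r} uses a non-amino-acid letter")
    position = int(pos_s)
    actual = tail.residue_at(position)
    if actual != ref:
        raise MutationMismatchError(
            f"{tail.name}: expected {ref} at precursor position {position}, found {actual}"
        )
    i = position - tail.start_index
    mutated = tail.residues[:i] + alt + tail.residues[i + 1 :]
    return replace(tail, name=f"{tail.name}_{spec}", residues=mutated)


def motif_presence_table(tails: Sequence[TailSequence]) -> pd.DataFrame:
    """Boolean presence of each motif class, one row per tail."""
    if not tails:
        raise InvalidParameterError("need at least one tail")
    rows = []
    for tail in tails:
        classes = {h.motif_class for h in find_motifs(tail)}
        rows.append(
            {
                "tail": tail.name,
                "species": tail.species,
                MEMBRANE_PROXIMAL: MEMBRANE_PROXIMAL in classes,
                MEMBRANE_DISTAL: MEMBRANE_DISTAL in classes,
            }
        )
    return pd.DataFrame(rows).set_index("tail")


# --- FASTA IO (header = name|start_index|species, spaces as underscores) ---

def read_tails_fasta(path: str | Path) -> list[TailSequence]:
    tails = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.description.split("|")
        name = parts[0].strip()
        start_index = int(parts[1]) if len(parts) > 1 and parts[1].strip() else 1
        species = parts[2].strip().replace("_", " ") if len(parts) > 2 else ""
        tails.append(
            TailSequence(
                name=name,
                residues=str(record.seq).upper(),
                start_index=start_index,
                species=species,
            )
        )
    return tails


def write_tails_fasta(tails: Iterable[TailSequence], path: str | Path) -> None:
    records = []
    for t in tails:
        header = f"{t.name}|{t.start_index}|{t.species.replace(' ', '_')}"
        records.append(SeqRecord(Seq(t.residues), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def load_packaged_tails(include_synthetic: bool = True) -> list[TailSequence]:
    """Load the packaged integrin beta tail panel.

    ``human_itgb_tails.fasta`` holds the human beta-1/2/3 tails
    reconstructed from the published construct boundaries and canonical
    tail sequences.  ``extended_itgb_tails.synthetic.fasta`` holds synthetic
    stand-ins for the remaining human tails and the two *Capsaspora
    owczarzaki* tails: sequences designed to carry the documented motif
    content of each tail (beta-8 lacking the proximal motif, the C.ow
    tails carrying NPxY/NPxF), not the authentic residues.
    """
    data_dir = Path(__file__).parent / "data"
    tails = read_tails_fasta(data_dir / "human_itgb_tails.fasta")
    if include_synthetic:
        tails += read_tails_fasta(data_dir / "extended_itgb_tails.synthetic.fasta")
    return tails
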