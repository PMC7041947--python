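"""Selectivity-filter sequence bookkeeping.

Homotetrameric bacterial Nav/Cav channels select ions at a seven-residue
pore-loop window. Positions are renumbered 1-7 locally (e.g. the CavMr
filter 183-TLEGWVD-189 becomes Thr1..Asp7), which is the convention behind
mutant names such as G4D or D7M. This module handles that renumbering,
mutation nomenclature, acidic-charge accounting for tetramers and
heteromeric assemblies, and per-position amino-acid frequency matrices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FilterSequence",
    "BUILTIN_FILTERS",
    "apply_mutation",
    "charge_count",
    "frequency_matrix",
    "filters_from_fasta",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: residues counted as negatively charged
ACIDIC = set("DE")
FILTER_LENGTH = 7


class MutationMismatchError(ValueError):
    """Mutation code's reference residue disagrees with the sequence."""


@dataclass(frozen=True)
class FilterSequence:
    """A 7-residue selectivity-filter window with local 1-7 numbering.

    ``parent_offset`` is the parent-sequence position of local position 1
    (e.g. 183 for CavMr), so parent position of residue i is
    parent_offset + i - 1.
    """

    residues: str
    parent_offset: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) != FILTER_LENGTH:
            raise ValueError(
                f"filter must be exactly {FILTER_LENGTH} residues, "
                f"got {len(self.residues)} ({self.residues!r})"
            )
        bad = set(self.residues.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def local_position(self, parent_position: int) -> int:
        """Renumber a parent-sequence position into the local 1-7 frame."""
        local = parent_position - self.parent_offset + 1
        if not 1 <= local <= FILTER_LENGTH:
            raise ValueError(
                f"parent position {parent_position} outside filter window "
                f"{self.parent_offset}-{self.parent_offset + FILTER_LENGTH - 1}"
            )
        return local

    def parent_position(self, local: int) -> int:
        """Inverse of :meth:`local_position`."""
        if not 1 <= local <= FILTER_LENGTH:
            raise ValueError(f"local position {local} outside 1-{FILTER_LENGTH}")
        return self.parent_offset + local - 1

    def residue(self, local: int) -> str:
        return self.residues[local - 1]


#: Filter strings with their channel labels. CavMr's window starts at
#: parent residue 183; offsets for the others are not used by any analysis
#: and default to 1.
BUILTIN_FILTERS: dict[str, FilterSequence] = {
    f.label: f
    for f in [
        FilterSequence("TLEGWVD", parent_offset=183, label="CavMr"),
        FilterSequence("TLEDWTD", label="NavPp"),
        FilterSequence("TLEGWVM", label="CavMr-D7M"),
        FilterSequence("TLDDWSD", label="CavAb"),  # NavAb-derived artificial Cav
        FilterSequence("TLDDWAD", label="NaChBac-CaMut"),
        FilterSequence("TLEDWSD", label="NavPp-T6S"),
        FilterSequence("TLEDWAD", label="NavPp-T6A"),
        FilterSequence("TLESWAS", label="NsvBa-ancestor"),
        FilterSequence("TLDSWGS", label="NsvBa"),
        FilterSequence("TVDGWTD", label="CatSper3"),
        FilterSequence("TQDGWVD", label="CatSper4"),
    ]
}


def _parse_code(code: str) -> tuple[str, int, str]:
    ref, pos_str, new = code[0], code[1:-1], code[-1]
    if ref not in AMINO_ACIDS or new not in AMINO_ACIDS or not pos_str.isdigit():
        raise ValueError(f"malformed mutation code {code!r}")
    return ref, int(pos_str), new


def apply_mutation(
    filter_seq: FilterSequence,
    mutation: str,
    parent_numbering: bool = False,
) -> FilterSequence:
    """Apply one or more point mutations like ``"G4D"`` or ``"T6S/D7M"``.

    Codes use local 1-7 numbering by default; set ``parent_numbering=True``
    for full-protein codes (e.g. G240A with the appropriate
    ``parent_offset``). Multi-mutation codes separated by ``/`` are
    applied left to right. The reference residue must match the current
    sequence at the stated position.
    """
    seq = filter_seq
    for code in mutation.split("/"):
        ref, pos, new = _parse_code(code.strip())
        local = seq.local_position(pos) if parent_numbering else pos
        if not 1 <= local <= FILTER_LENGTH:
            raise ValueError(f"position {pos} outside 1-{FILTER_LENGTH}")
        found = seq.residue(local)
        if found != ref:
            raise MutationMismatchError(
                f"mutation {code}: expected {ref} at position {local}, "
                f"sequence {seq.residues!r} has {found}"
            )
        residues = seq.residues[: local - 1] + new + seq.residues[local:]
        seq = FilterSequence(
            residues, seq.parent_offset,
            label=f"{seq.label}-{code}" if seq.label else code,
        )
    return seq


def charge_count(
    filters: FilterSequence | Sequence[FilterSequence],
    n_subunits: int = 4,
) -> dict[str, int]:
    """Acidic-residue accounting for a channel assembly.

    For a single filter, counts are per subunit times ``n_subunits``
    (homotetramer by default). For a sequence of filters (a heteromeric
    assembly, e.g. the four subdomains of a mammalian Cav), each filter
    contributes once and ``n_subunits`` is ignored.

    Returns aspartates and net negative (D + E) per subunit and per
    assembly. Only D and E are counted; no residue contributes positive
    charge.
    """
    if isinstance(filters, FilterSequence):
        subunits = [filters] * n_subunits
        per_subunit = filters
    else:
        subunits = list(filters)
        per_subunit = None
        if not subunits:
            raise ValueError("empty filter list")

    def acidic(seq: FilterSequence) -> int:
        return sum(1 for r in seq.residues if r in ACIDIC)

    def aspartates(seq: FilterSequence) -> int:
        return seq.residues.count("D")

    out = {
        "aspartates_per_assembly": sum(aspartates(s) for s in subunits),
        "net_negative_per_assembly": sum(acidic(s) for s in subunits),
        "n_subunits": len(subunits),
    }
    if per_subunit is not None:
        out["aspartates_per_subunit"] = aspartates(per_subunit)
        out["net_negative_per_subunit"] = acidic(per_subunit)
    return out


def frequency_matrix(filters: Iterable[FilterSequence]) -> pd.DataFrame:
    """Per-position amino-acid appearance frequencies.

    Rows are amino acids, columns local positions 1-7; every column sums
    to 1. Attaches the number of sequences as ``df.attrs['n_sequences']``.
    """
    seqs = [f.residues for f in filters]
    if not seqs:
        raise ValueError("no sequences given")
    counts = {
        pos: Counter(seq[pos - 1] for seq in seqs)
        for pos in range(1, FILTER_LENGTH + 1)
    }
    aas = sorted(AMINO_ACIDS)
    data = {
        pos: [counts[pos].get(aa, 0) / len(seqs) for aa in aas]
        for pos in range(1, FILTER_LENGTH + 1)
    }
    df = pd.DataFrame(data, index=aas)
    df.attrs["n_sequences"] = len(seqs)
    return df


def filters_from_fasta(
    path: str | Path, offset: int, label_from_id: bool = True
) -> list[FilterSequence]:
    """Extract 7-residue filter windows from parent sequences in FASTA.

    ``offset`` is the 1-based parent position of filter position 1 (the
    same offset is applied to every record).
    """
    from Bio import SeqIO

    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        window = seq[offset - 1: offset - 1 + FILTER_LENGTH]
        out.append(
            FilterSequence(
                window, parent_offset=offset,
                label=record.id if label_from_id else "",
            )
        )
    return out
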