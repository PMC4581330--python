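"""Core data containers shared across the package.

A :class:`ProteinRecord` is the unit of a corpus: an amino-acid sequence with
per-residue binary disorder labels (``'1'`` = disordered) and optional
annotations — a multiple sequence alignment, predicted secondary structure,
predicted solvent accessibility and structural template hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

SS_ALPHABET = "HEC"  # helix, strand, coil
SA_ALPHABET = "BbeE"  # completely buried, partly buried, partly exposed, exposed


@dataclass
class TemplateHit:
    """A structural template aligned to the query.

    ``identity`` is the sequence identity between query and template in
    (0, 1].  ``annotation`` is a string over ``{O, D, -}`` of the query's
    length: per-residue order/disorder state transferred from the template,
    with ``'-'`` marking query positions the template does not cover.
    """

    template_id: str
    identity: float
    annotation: str

    def __post_init__(self) -> None:
        if not 0.0 < self.identity <= 1.0:
            raise ValueError(
                f"template {self.template_id}: identity {self.identity} "
                "outside (0, 1]"
            )
        bad = set(self.annotation) - set("OD-")
        if bad:
            raise ValueError(
                f"template {self.template_id}: annotation symbols {sorted(bad)} "
                "outside {'O', 'D', '-'}"
            )


@dataclass
class MultipleAlignment:
    """An MSA of the query against homologous sequences.

    All rows have equal length; the query row contains no gaps (columns where
    the query is gapped are dropped upstream, so query coordinates define
    positions).
    """

    rows: list[str]
    query_row: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("ragged alignment: rows have unequal lengths")
        if not 0 <= self.query_row < len(self.rows):
            raise ValueError("query_row out of range")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def query(self) -> str:
        return self.rows[self.query_row]


@dataclass
class ProteinRecord:
    """A protein chain with labels and optional annotations."""

    id: str
    sequence: str
    labels: str | None = None
    resolution: float | None = None
    msa: MultipleAlignment | None = None
    ss: str | None = None
    sa: str | None = None
    template_hits: list[TemplateHit] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.labels is not None:
            if len(self.labels) != len(self.sequence):
                raise ValueError(
                    f"record {self.id}: labels length {len(self.labels)} != "
                    f"sequence length {len(self.sequence)}"
                )
            if set(self.labels) - {"0", "1"}:
                raise ValueError(f"record {self.id}: labels must be over {{0,1}}")

    def __len__(self) -> int:
        return len(self.sequence)


def disordered_runs(labels: str) -> list[tuple[int, int]]:
    """Maximal runs of '1' in a label string as (start, length) pairs (0-based)."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(labels):
        if c == "1" and start is None:
            start = i
        elif c != "1" and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(labels) - start))
    return runs


@dataclass
class FoldSplit:
    """Assignment of record ids to cross-validation folds."""

    fold_assignments: dict[str, int]
    n_folds: int = 5

    def __post_init__(self) -> None:
        folds = set(self.fold_assignments.values())
        if folds and not folds <= set(range(self.n_folds)):
            raise ValueError("fold index outside 0..n_folds-1")

    def ids_in_fold(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_assignments.items() if f == fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.fold_assignments.values():
            sizes[f] += 1
        return sizes
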