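"""Synthetic corpus generator.

Emulates the statistical structure the disorder predictor assumes so the full
pipeline is exercisable without external searches or databases: chains longer
than 50 residues carrying disordered runs of 3-30 consecutive residues at a
~6% residue prevalence, MSAs whose conservation depends on the order/disorder
state, predicted secondary-structure and solvent-accessibility strings coupled
to the labels, and template hits with controlled identity and annotation noise.

The disorder signal is planted in residue composition: disordered positions
are drawn from a distribution enriched in P/E/S/K/Q/G and depleted in
W/C/F/I/Y/V (the classic disorder-promoting/order-promoting split), ordered
positions from the complementary bias, so the mapping is learnable from
sequence alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (
    AMINO_ACIDS,
    MultipleAlignment,
    ProteinRecord,
    TemplateHit,
)

DISORDER_PROMOTING = "PESKQG"
ORDER_PROMOTING = "WCFIYV"


def _composition(enrich: str, deplete: str, up: float, down: float) -> np.ndarray:
    w = np.ones(len(AMINO_ACIDS))
    for aa in enrich:
        w[AMINO_ACIDS.index(aa)] *= up
    for aa in deplete:
        w[AMINO_ACIDS.index(aa)] *= down
    return w / w.sum()


#: residue distribution at disordered positions
DISORDER_COMPOSITION = _composition(DISORDER_PROMOTING, ORDER_PROMOTING, 2.5, 0.3)
#: residue distribution at ordered positions
ORDER_COMPOSITION = _composition(ORDER_PROMOTING, DISORDER_PROMOTING, 1.8, 0.5)

# gap emission is a sub-event of a mutation event: a mutated alignment cell
# becomes a gap with this probability, otherwise a substituted residue.  Zero
# mutation rate therefore implies zero gaps.
GAP_GIVEN_MUTATION = 0.1

# probability that the label-typical structural class is emitted by the
# synthetic secondary-structure / solvent-accessibility annotators
SS_SA_FIDELITY = 0.85

# probability a template hit covers only a contiguous fragment of the query
FRAGMENT_PROBABILITY = 0.3


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic corpus.

    Defaults mirror the dataset the predictor targets: chains of length
    80-300 (all > 50), disordered runs of 3-30 residues, 6% residue-level
    disorder prevalence.
    """

    n_chains: int = 200
    length_range: tuple[int, int] = (80, 300)
    disorder_run_range: tuple[int, int] = (3, 30)
    target_disorder_fraction: float = 0.06
    msa_depth: int = 30
    mutation_rate_ordered: float = 0.1
    mutation_rate_disordered: float = 0.4
    template_identities: tuple[float, ...] = (0.9, 0.6, 0.3)
    template_label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.disorder_run_range
        if not 1 <= lo <= hi:
            raise ValueError("disorder_run_range must satisfy 1 <= lo <= hi")
        if hi > self.length_range[1]:
            raise ValueError("disorder_run_range exceeds maximum chain length")
        for name in (
            "mutation_rate_ordered",
            "mutation_rate_disordered",
            "template_label_noise",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.target_disorder_fraction < 1.0:
            raise ValueError("target_disorder_fraction must lie in [0, 1)")
        if self.mutation_rate_disordered < self.mutation_rate_ordered:
            raise ValueError(
                "mutation_rate_disordered must be >= mutation_rate_ordered"
            )


def _partition_run_lengths(
    total: int, run_range: tuple[int, int], rng: np.random.Generator
) -> list[int]:
    """Split a disordered-residue budget into run lengths within run_range."""
    rmin, rmax = run_range
    runs: list[int] = []
    t = total
    while t > 0:
        can_split = t - rmin >= rmin and min(rmax, t - rmin) >= rmin
        if t <= rmax and (not can_split or rng.random() < 0.5):
            runs.append(t)
            t = 0
        else:
            r = int(rng.integers(rmin, min(rmax, t - rmin) + 1))
            runs.append(r)
            t -= r
    return runs


def generate_chain(
    config: SyntheticConfig, rng: np.random.Generator
) -> ProteinRecord:
    """Generate one labelled chain.

    Every maximal disordered run has length within ``disorder_run_range`` and
    runs are separated by at least one ordered residue, so run boundaries
    survive label scanning.
    """
    lo, hi = config.length_range
    if lo <= 50:
        raise ValueError(
            "length_range lower bound must exceed 50 (shorter chains would be "
            "discarded by the dataset length filter)"
        )
    length = int(rng.integers(lo, hi + 1))

    labels = np.zeros(length, dtype=np.int8)
    if config.target_disorder_fraction > 0.0:
        rmin, _ = config.disorder_run_range
        budget = max(rmin, round(length * config.target_disorder_fraction))
        budget = min(budget, length // 2)  # leave room for separators
        runs = _partition_run_lengths(budget, config.disorder_run_range, rng)
        k = len(runs)
        ordered = length - sum(runs)
        # distribute ordered residues into k+1 gaps, internal gaps >= 1
        extra = ordered - (k - 1)
        gaps = rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
        pos = int(gaps[0])
        for i, r in enumerate(runs):
            labels[pos : pos + r] = 1
            pos += r + int(gaps[i + 1]) + (1 if i < k - 1 else 0)

    aa = np.array(list(AMINO_ACIDS))
    seq = np.where(
        labels == 1,
        rng.choice(aa, size=length, p=DISORDER_COMPOSITION),
        rng.choice(aa, size=length, p=ORDER_COMPOSITION),
    )
    rec_id = f"syn{rng.integers(0, 10**9):09d}"
    return ProteinRecord(
        id=rec_id,
        sequence="".join(seq),
        labels="".join(labels.astype(str)),
    )


def generate_msa(
    record: ProteinRecord, config: SyntheticConfig, rng: np.random.Generator
) -> MultipleAlignment:
    """Generate an MSA for a chain with order/disorder-dependent conservation.

    Row 0 is the query.  Each other row mutates every position independently
    at ``mutation_rate_ordered`` or ``mutation_rate_disordered`` according to
    the label; a mutation emits a gap with probability 0.1, otherwise a
    residue drawn from the label's composition.
    """
    if config.msa_depth < 1:
        raise ValueError("msa_depth must be >= 1")
    n = len(record.sequence)
    labels = np.frombuffer(record.labels.encode(), dtype=np.int8) - ord("0")
    rate = np.where(
        labels == 1, config.mutation_rate_disordered, config.mutation_rate_ordered
    )
    aa = np.array(list(AMINO_ACIDS))
    rows = [record.sequence]
    for _ in range(config.msa_depth - 1):
        row = np.array(list(record.sequence))
        mutate = rng.random(n) < rate
        if mutate.any():
            gap = rng.random(n) < GAP_GIVEN_MUTATION
            subs_dis = rng.choice(aa, size=n, p=DISORDER_COMPOSITION)
            subs_ord = rng.choice(aa, size=n, p=ORDER_COMPOSITION)
            subs = np.where(labels == 1, subs_dis, subs_ord)
            row[mutate & gap] = "-"
            row[mutate & ~gap] = subs[mutate & ~gap]
        rows.append("".join(row))
    return MultipleAlignment(rows=rows, query_row=0)


def generate_ss(
    record: ProteinRecord, rng: np.random.Generator
) -> str:
    """Synthetic 3-class secondary-structure string coupled to the labels."""
    out = []
    for c in record.labels:
        if c == "1":
            out.append("C" if rng.random() < SS_SA_FIDELITY else rng.choice(["H", "E"]))
        else:
            out.append(
                rng.choice(["H", "E"]) if rng.random() < SS_SA_FIDELITY else "C"
            )
    return "".join(out)


def generate_sa(
    record: ProteinRecord, rng: np.random.Generator
) -> str:
    """Synthetic 4-class solvent-accessibility string coupled to the labels."""
    out = []
    for c in record.labels:
        exposed = rng.random() < SS_SA_FIDELITY
        if c == "0":
            exposed = not exposed
        out.append(rng.choice(["e", "E"]) if exposed else rng.choice(["B", "b"]))
    return "".join(out)


def generate_template_hits(
    record: ProteinRecord, config: SyntheticConfig, rng: np.random.Generator
) -> list[TemplateHit]:
    """One hit per requested identity; annotations are the true labels with
    independent flips at ``template_label_noise``; a hit may cover only a
    contiguous fragment of the query (uncovered positions are '-')."""
    n = len(record.sequence)
    labels = np.frombuffer(record.labels.encode(), dtype=np.int8) - ord("0")
    hits = []
    for k, ident in enumerate(config.template_identities):
        if not 0.0 < ident <= 1.0:
            raise ValueError(f"template identity {ident} outside (0, 1]")
        flips = rng.random(n) < config.template_label_noise
        ann = np.where(labels ^ flips, "D", "O")
        if rng.random() < FRAGMENT_PROBABILITY and n > 4:
            frac = rng.uniform(0.5, 0.9)
            cov = max(1, int(round(n * frac)))
            start = int(rng.integers(0, n - cov + 1))
            mask = np.zeros(n, dtype=bool)
            mask[start : start + cov] = True
            ann = np.where(mask, ann, "-")
        hits.append(
            TemplateHit(
                template_id=f"{record.id}_t{k}",
                identity=float(ident),
                annotation="".join(ann),
            )
        )
    return hits


def generate_corpus(config: SyntheticConfig) -> list[ProteinRecord]:
    """Generate a fully annotated corpus, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_chains):
        rec = generate_chain(config, rng)
        rec.id = f"syn{i:04d}"
        rec.msa = generate_msa(rec, config, rng)
        rec.ss = generate_ss(rec, rng)
        rec.sa = generate_sa(rec, rng)
        rec.template_hits = generate_template_hits(rec, config, rng)
        records.append(rec)
    return records
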