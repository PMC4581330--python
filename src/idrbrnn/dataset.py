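"""Corpus curation: chain filtering, redundancy reduction and fold splitting.

The predictor targets *short* disorder: a chain enters the corpus only if it
is longer than 50 residues and all of its disordered runs are 3-30 residues
long (with at least one such run present).  Redundancy reduction removes the
lesser-quality member of any pair above 30% mutual sequence identity.
"""

from __future__ import annotations

import logging

import numpy as np

from .records import FoldSplit, ProteinRecord, disordered_runs

logger = logging.getLogger(__name__)


def filter_chains(
    records: list[ProteinRecord],
    min_len: int = 50,
    run_range: tuple[int, int] = (3, 30),
    max_resolution: float = 2.0,
) -> list[ProteinRecord]:
    """Keep chains with length > min_len, at least one disordered run within
    ``run_range``, no run longer than the upper bound, and (when a resolution
    is recorded) resolution strictly below ``max_resolution`` Angstrom.

    The run rule is read strictly: a chain containing *any* run longer than
    the upper bound is rejected even if it also carries a valid short run.
    """
    rmin, rmax = run_range
    kept = []
    for rec in records:
        if rec.labels is None:
            raise ValueError(f"record {rec.id} has no disorder labels")
        if len(rec) <= min_len:
            continue
        if rec.resolution is not None and rec.resolution >= max_resolution:
            continue
        lengths = [ln for _, ln in disordered_runs(rec.labels)]
        if not any(rmin <= ln <= rmax for ln in lengths):
            continue
        if any(ln > rmax for ln in lengths):
            continue
        kept.append(rec)
    return kept


def _quality_key(rec: ProteinRecord) -> tuple:
    """Sort key: smaller = better.

    Resolved structures outrank unresolved ones; among resolved, lower
    Angstrom wins; among unresolved, longer chain wins; ties broken by id
    (lexicographically smaller id survives).
    """
    if rec.resolution is not None:
        return (0, rec.resolution, rec.id)
    return (1, -len(rec), rec.id)


def identity_from_alignment(a: str, b: str) -> float:
    """Fallback pairwise identity: global alignment, match=1/mismatch=0,
    gaps ignored, normalised by the shorter sequence length."""
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    aln = aligner.align(a, b)[0]
    matches = sum(
        1
        for sa, sb in zip(aln[0], aln[1])
        if sa == sb and sa != "-"
    )
    return matches / min(len(a), len(b))


def compute_identity_matrix(records: list[ProteinRecord]) -> np.ndarray:
    n = len(records)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = identity_from_alignment(
                records[i].sequence, records[j].sequence
            )
    return mat


def read_identity_tsv(path, ids: list[str]) -> np.ndarray:
    """Pairwise identity matrix from a TSV of (id, id, identity) rows,
    ordered to match ``ids``; diagonal 1, symmetric; missing pairs are NaN
    (rejected downstream)."""
    index = {rid: i for i, rid in enumerate(ids)}
    mat = np.full((len(ids), len(ids)), np.nan)
    np.fill_diagonal(mat, 1.0)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            a, b, v = line.rstrip("\n").split("\t")
            if a in index and b in index:
                mat[index[a], index[b]] = mat[index[b], index[a]] = float(v)
    return mat


def redundancy_reduce(
    records: list[ProteinRecord],
    pairwise_identity: np.ndarray,
    threshold: float = 0.30,
) -> list[ProteinRecord]:
    """Remove the lesser-quality member of every pair with mutual identity
    strictly above ``threshold`` until no retained pair conflicts.

    Greedy rule: while conflicts remain, drop the worst-quality record among
    those involved in any conflict.
    """
    n = len(records)
    mat = np.asarray(pairwise_identity, dtype=float)
    if mat.shape != (n, n):
        raise ValueError(
            f"identity matrix shape {mat.shape} does not match {n} records"
        )
    if np.isnan(mat).any():
        raise ValueError("identity matrix contains missing entries")
    alive = list(range(n))
    while True:
        conflicted = set()
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                i, j = alive[ai], alive[bi]
                if mat[i, j] > threshold:
                    conflicted.add(i)
                    conflicted.add(j)
        if not conflicted:
            break
        worst = max(conflicted, key=lambda i: _quality_key(records[i]))
        alive.remove(worst)
    return [records[i] for i in alive]


def make_folds(
    records: list[ProteinRecord], k: int = 5, seed: int = 0
) -> FoldSplit:
    """Split chains into k folds balanced to +-1 chain, uniformly at random
    under the seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"cannot split {len(records)} records into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    assignments = {records[int(i)].id: int(pos % k) for pos, i in enumerate(order)}
    split = FoldSplit(fold_assignments=assignments, n_folds=k)
    res_per_fold = [0] * k
    for rec in records:
        res_per_fold[assignments[rec.id]] += len(rec)
    logger.info(
        "fold residue counts: %s (imbalance %d)",
        res_per_fold,
        max(res_per_fold) - min(res_per_fold),
    )
    return split


def write_folds(split: FoldSplit, path) -> None:
    with open(path, "w") as fh:
        for rid, fold in sorted(split.fold_assignments.items()):
            fh.write(f"{rid}\t{fold}\n")


def read_folds(path, k: int = 5) -> FoldSplit:
    assignments = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rid, fold = line.split("\t")
                assignments[rid] = int(fold)
    return FoldSplit(fold_assignments=assignments, n_folds=k)
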