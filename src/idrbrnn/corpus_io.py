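"""Reading and writing a corpus directory.

Layout::

    corpus/
      sequences.fasta         amino-acid sequences
      labels.fasta            0/1 disorder label strings (FASTA-like)
      ss.fasta                H/E/C secondary-structure strings (optional)
      sa.fasta                B/b/e/E solvent-accessibility strings (optional)
      msa/<id>.afa            one aligned FASTA per chain (optional)
      templates/<id>.tsv      template hits: template_id, identity, annotation
      manifest.json           seed, counts, prevalence
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import MultipleAlignment, ProteinRecord, TemplateHit


def _write_fasta(path: Path, items: list[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    SeqIO.write(recs, str(path), "fasta")


def _read_fasta(path: Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_corpus(records: list[ProteinRecord], outdir: str | Path,
                 seed: int | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(out / "sequences.fasta", [(r.id, r.sequence) for r in records])
    if all(r.labels is not None for r in records):
        _write_fasta(out / "labels.fasta", [(r.id, r.labels) for r in records])
    if all(r.ss is not None for r in records):
        _write_fasta(out / "ss.fasta", [(r.id, r.ss) for r in records])
    if all(r.sa is not None for r in records):
        _write_fasta(out / "sa.fasta", [(r.id, r.sa) for r in records])
    msadir = out / "msa"
    tdir = out / "templates"
    for r in records:
        if r.msa is not None:
            msadir.mkdir(exist_ok=True)
            _write_fasta(
                msadir / f"{r.id}.afa",
                [(f"{r.id}_row{k}", row) for k, row in enumerate(r.msa.rows)],
            )
        if r.template_hits is not None:
            tdir.mkdir(exist_ok=True)
            with open(tdir / f"{r.id}.tsv", "w") as fh:
                fh.write("template_id\tidentity\tannotation\n")
                for h in r.template_hits:
                    fh.write(f"{h.template_id}\t{h.identity:.6f}\t{h.annotation}\n")
    n_res = sum(len(r) for r in records)
    n_dis = sum(r.labels.count("1") for r in records if r.labels)
    manifest = {
        "n_chains": len(records),
        "n_residues": n_res,
        "disorder_prevalence": (n_dis / n_res) if n_res else 0.0,
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_template_tsv(path: str | Path) -> list[TemplateHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("template_id"):
            raise ValueError(f"{path}: missing template TSV header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tid, ident, ann = line.split("\t")
            hits.append(TemplateHit(tid, float(ident), ann))
    return hits


def read_corpus(indir: str | Path) -> list[ProteinRecord]:
    d = Path(indir)
    seqs = _read_fasta(d / "sequences.fasta")
    labels = _read_fasta(d / "labels.fasta") if (d / "labels.fasta").exists() else {}
    ss = _read_fasta(d / "ss.fasta") if (d / "ss.fasta").exists() else {}
    sa = _read_fasta(d / "sa.fasta") if (d / "sa.fasta").exists() else {}
    records = []
    for rid, seq in seqs.items():
        msa = None
        msa_path = d / "msa" / f"{rid}.afa"
        if msa_path.exists():
            rows = [str(r.seq) for r in SeqIO.parse(str(msa_path), "fasta")]
            msa = MultipleAlignment(rows=rows, query_row=0)
        hits = None
        t_path = d / "templates" / f"{rid}.tsv"
        if t_path.exists():
            hits = read_template_tsv(t_path)
        records.append(
            ProteinRecord(
                id=rid,
                sequence=seq,
                labels=labels.get(rid),
                msa=msa,
                ss=ss.get(rid),
                sa=sa.get(rid),
                template_hits=hits,
            )
        )
    return records
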