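"""Reading, sanitizing, filtering and class-balancing transcript sets.

The preprocessing mirrors the usual lncRNA-classification pipeline: drop
transcripts shorter than 200 nt, remove near-duplicate sequences with a
greedy longest-first clustering step, then randomly down-sample the
majority class so lncRNAs and protein-coding transcripts (PCTs) are
equally represented.
"""

from __future__ import annotations

import json
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LNCRNA = "lncRNA"
PCT = "PCT"
LABELS = (LNCRNA, PCT)

_NON_ACGT = re.compile(r"[^ACGT]")


def sanitize_sequence(raw: str) -> str:
    """Uppercase, map U->T, collapse anything outside {A,C,G,T} to N."""
    return _NON_ACGT.sub("N", raw.upper().replace("U", "T"))


@dataclass(frozen=True)
class Transcript:
    """One sequence record: identifier, cleaned sequence, optional label."""

    id: str
    seq: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript identifier must be non-empty")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"label must be one of {LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Dataset:
    """Ordered transcript collection plus a processing log."""

    records: list[Transcript] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            key = r.label if r.label is not None else "unlabeled"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def log(self, stage: str, **info) -> None:
        self.provenance.append({"stage": stage, **info})

    def write_provenance(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for entry in self.provenance:
                fh.write(json.dumps(entry) + "\n")


def read_fasta(
    path: str | Path,
    label: str | None = None,
    label_map: dict[str, str] | None = None,
) -> Dataset:
    """Read a FASTA file into a Dataset, sanitizing sequences.

    Labels come either from ``label`` (one file per class) or from a
    per-identifier ``label_map``; records absent from the map stay
    unlabeled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate identifier in {path}: {rec.id!r}")
        seen.add(rec.id)
        lab = label if label is not None else (label_map or {}).get(rec.id)
        records.append(Transcript(rec.id, sanitize_sequence(str(rec.seq)), lab))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ds = Dataset(records)
    ds.log("read_fasta", path=str(path), n=len(records))
    return ds


def merge(*datasets: Dataset) -> Dataset:
    """Concatenate datasets, enforcing globally unique identifiers."""
    records: list[Transcript] = []
    seen: set[str] = set()
    prov: list[dict] = []
    for ds in datasets:
        for r in ds.records:
            if r.id in seen:
                raise ValueError(f"duplicate identifier across inputs: {r.id!r}")
            seen.add(r.id)
            records.append(r)
        prov.extend(ds.provenance)
    out = Dataset(records, prov)
    out.log("merge", n=len(records))
    return out


def read_label_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id, label) -> mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            ident, lab = parts
            if lab not in LABELS:
                raise ValueError(f"{path}:{lineno}: unknown label {lab!r}")
            mapping[ident] = lab
    return mapping


def write_label_map(ds: Dataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ds.records:
            if r.label is None:
                raise ValueError(f"transcript {r.id!r} has no label to write")
            fh.write(f"{r.id}\t{r.label}\n")


def filter_short(ds: Dataset, min_len: int = 200) -> Dataset:
    """Drop every transcript shorter than ``min_len`` (>= min_len kept)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in ds.records if len(r.seq) >= min_len]
    out = Dataset(kept, list(ds.provenance))
    out.log("filter_short", min_len=min_len, before=len(ds), after=len(kept))
    return out


def _canonical_kmers(seq: str, k: int = 8) -> frozenset[str]:
    comp = str.maketrans("ACGT", "TGCA")
    kmers = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        rc = w.translate(comp)[::-1]
        kmers.add(min(w, rc))
    return frozenset(kmers)


def kmer_identity(a: str, b: str, k: int = 8) -> float:
    """Alignment-free identity: shared canonical k-mers over the smaller set."""
    ka, kb = _canonical_kmers(a, k), _canonical_kmers(b, k)
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 1.0 if a == b else 0.0
    return len(ka & kb) / denom


def greedy_dedup(ds: Dataset, identity: float = 0.9, k: int = 8) -> Dataset:
    """Greedy longest-first redundancy removal.

    Sequences are processed longest first (stable tie-break by input
    order). A sequence whose canonical-k-mer identity to any retained
    representative reaches ``identity`` is absorbed; otherwise it becomes
    a new representative. Deterministic for a fixed input.
    """
    if not (0.0 < identity <= 1.0):
        raise ValueError("identity must be in (0, 1]")
    if not ds.records:
        raise ValueError("cannot deduplicate an empty dataset")
    order = sorted(range(len(ds.records)), key=lambda i: (-len(ds.records[i].seq), i))
    reps: list[int] = []
    rep_kmers: list[frozenset[str]] = []
    rep_seqs: list[str] = []
    # inverted index k-mer -> representative positions, to skip hopeless pairs
    index: dict[str, list[int]] = {}
    for idx in order:
        rec = ds.records[idx]
        km = _canonical_kmers(rec.seq, k)
        absorbed = False
        if km:
            shared: dict[int, int] = {}
            for w in km:
                for rpos in index.get(w, ()):
                    shared[rpos] = shared.get(rpos, 0) + 1
            for rpos, cnt in shared.items():
                denom = min(len(km), len(rep_kmers[rpos]))
                if denom and cnt / denom >= identity:
                    absorbed = True
                    break
        else:
            # k-mer-free (short/N-rich) sequences: absorb only exact copies
            absorbed = rec.seq in rep_seqs
        if not absorbed:
            rpos = len(reps)
            reps.append(idx)
            rep_kmers.append(km)
            rep_seqs.append(rec.seq)
            for w in km:
                index.setdefault(w, []).append(rpos)
    kept = [ds.records[i] for i in reps]
    out = Dataset(kept, list(ds.provenance))
    out.log("greedy_dedup", identity=identity, k=k, before=len(ds), after=len(kept))
    return out


def cdhit_est_dedup(ds: Dataset, identity: float = 0.9) -> Dataset:
    """Deduplicate with an externally installed cd-hit-est, if present.

    Falls back is not implicit: callers should check :func:`cdhit_available`
    and use :func:`greedy_dedup` otherwise.
    """
    if not cdhit_available():
        raise RuntimeError("cd-hit-est is not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        write_fasta(ds, fin)
        subprocess.run(
            ["cd-hit-est", "-i", str(fin), "-o", str(fout), "-c", str(identity)],
            check=True,
            capture_output=True,
        )
        kept_ids = {rec.id for rec in SeqIO.parse(str(fout), "fasta")}
    kept = [r for r in ds.records if r.id in kept_ids]
    out = Dataset(kept, list(ds.provenance))
    out.log("cdhit_est_dedup", identity=identity, before=len(ds), after=len(kept))
    return out


def cdhit_available() -> bool:
    return shutil.which("cd-hit-est") is not None


def balance_downsample(ds: Dataset, seed: int) -> Dataset:
    """Down-sample the majority class to the minority-class size.

    Sampling is without replacement with the given seed; the minority
    class is untouched; original record order is preserved.
    """
    for r in ds.records:
        if r.label is None:
            raise ValueError(f"transcript {r.id!r} is unlabeled; cannot balance")
    by_label: dict[str, list[int]] = {}
    for i, r in enumerate(ds.records):
        by_label.setdefault(r.label, []).append(i)
    if len(by_label) < 2:
        raise ValueError("both classes must be present to balance")
    minority = min(len(v) for v in by_label.values())
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for lab in sorted(by_label):
        idxs = by_label[lab]
        if len(idxs) > minority:
            chosen = rng.choice(len(idxs), size=minority, replace=False)
            keep.update(idxs[j] for j in chosen)
        else:
            keep.update(idxs)
    kept = [r for i, r in enumerate(ds.records) if i in keep]
    out = Dataset(kept, list(ds.provenance))
    out.log(
        "balance_downsample",
        seed=seed,
        before=ds.label_counts(),
        after=out.label_counts(),
    )
    return out


def write_fasta(ds: Dataset, path: str | Path) -> None:
    """Write a Dataset as 60-column-wrapped FASTA (round-trips exactly)."""
    recs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in ds.records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
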