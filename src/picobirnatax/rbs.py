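"""Prokaryotic ribosomal-binding-site (Shine-Dalgarno) motif scanning.

For every annotated ORF, the 24 nucleotides immediately upstream of its
start codon are extracted and searched for the canonical bacterial RBS
hexamer AGGAGG, its 5-mer fragments (AGGAG, GGAGG), and its 4-mer
fragments (AGGA, GGAG, GAGG). Each ORF is assigned the longest motif class
with at least one occurrence wholly inside the window — classes are
mutually exclusive, so per-dataset 4/5/6-mer counts sum to the total
number of motif-bearing ORFs. Enrichment of these motifs upstream of start
codons is evidence of translation by bacterial ribosomes, i.e. that the
virus is a bacteriophage.

Coordinates are 0-based half-open in memory and 1-based inclusive at file
interfaces (GenBank, GFF3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

WINDOW = 24
MOTIFS_6 = ("AGGAGG",)
MOTIFS_5 = ("AGGAG", "GGAGG")
MOTIFS_4 = ("AGGA", "GGAG", "GAGG")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ORF:
    orf_id: str
    start: int  # 0-based, first base of start codon (plus strand)
    end: int  # 0-based exclusive
    strand: int = 1


@dataclass
class AnnotatedSegment:
    """A genome segment sequence with its annotated ORFs."""

    segment_id: str
    sequence: str
    orfs: list[ORF]
    dataset_label: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        for orf in self.orfs:
            if not (0 <= orf.start < orf.end <= len(self.sequence)):
                raise ValueError(
                    f"ORF {orf.orf_id!r} coordinates [{orf.start}, {orf.end})"
                    f" outside segment {self.segment_id!r} "
                    f"(length {len(self.sequence)})"
                )


@dataclass(frozen=True)
class MotifHit:
    """Longest-class RBS motif found in one ORF's upstream window."""

    orf_id: str
    motif_class: str  # "6-mer" | "5-mer" | "4-mer" | "none"
    matched: Optional[str]
    offset: Optional[int]  # match start within the window
    window: str = ""
    truncated: bool = False


def filter_segments(
    segments: Iterable[AnnotatedSegment], min_utr: int = WINDOW
) -> list[AnnotatedSegment]:
    """Keep segments whose 5'-most ORF has a full upstream window.

    A plus-strand ORF needs ``min_utr`` bases before its start codon; a
    minus-strand ORF needs them after its end. Segments without ORFs are
    dropped with a warning.
    """
    kept = []
    for seg in segments:
        if not seg.orfs:
            warnings.warn(f"segment {seg.segment_id!r} has no ORFs; dropped")
            continue
        utrs = []
        for orf in seg.orfs:
            if orf.strand >= 0:
                utrs.append(orf.start)
            else:
                utrs.append(len(seg.sequence) - orf.end)
        # the 5'-most ORF is the one with the smallest upstream room
        if min(utrs) >= min_utr:
            kept.append(seg)
    return kept


def extract_upstream(
    segment: AnnotatedSegment, orf_id: str, window: int = WINDOW
) -> tuple[str, bool]:
    """The ``window`` bases immediately preceding an ORF's start codon.

    Minus-strand ORFs are reverse-complemented into plus orientation first
    (with a warning). If fewer than ``window`` bases are available for a
    non-5'-most ORF the window is shortened and flagged; returns
    ``(window_sequence, truncated)``.
    """
    orf = next((o for o in segment.orfs if o.orf_id == orf_id), None)
    if orf is None:
        raise KeyError(f"no ORF {orf_id!r} in segment {segment.segment_id!r}")
    if orf.strand >= 0:
        lo = max(0, orf.start - window)
        win = segment.sequence[lo : orf.start]
    else:
        warnings.warn(
            f"ORF {orf_id!r} is minus-strand; scanning its reverse complement"
        )
        hi = min(len(segment.sequence), orf.end + window)
        win = revcomp(segment.sequence[orf.end : hi])
    return win, len(win) < window


def classify_window(window: str, orf_id: str = "") -> MotifHit:
    """Assign the longest RBS motif class with a match inside the window.

    Precedence is 6-mer > 5-mer > 4-mer; within a class the leftmost match
    is reported. Matching is exact, so ambiguity codes never match.
    """
    window = window.upper()
    for cls, motifs in (
        ("6-mer", MOTIFS_6),
        ("5-mer", MOTIFS_5),
        ("4-mer", MOTIFS_4),
    ):
        hits = [
            (idx, m)
            for m in motifs
            if (idx := window.find(m)) != -1
        ]
        if hits:
            idx, m = min(hits)
            return MotifHit(
                orf_id=orf_id,
                motif_class=cls,
                matched=m,
                offset=idx,
                window=window,
            )
    return MotifHit(
        orf_id=orf_id, motif_class="none", matched=None, offset=None,
        window=window,
    )


def scan_segments(
    segments: Iterable[AnnotatedSegment], window: int = WINDOW
) -> pd.DataFrame:
    """Per-ORF motif hits for a batch of segments."""
    rows = []
    for seg in segments:
        for orf in seg.orfs:
            win, truncated = extract_upstream(seg, orf.orf_id, window=window)
            hit = classify_window(win, orf_id=orf.orf_id)
            rows.append(
                {
                    "dataset_label": seg.dataset_label,
                    "segment_id": seg.segment_id,
                    "orf_id": orf.orf_id,
                    "motif_class": hit.motif_class,
                    "matched": hit.matched or "",
                    "offset": hit.offset if hit.offset is not None else -1,
                    "window": hit.window,
                    "truncated": truncated,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dataset_label", "segment_id", "orf_id", "motif_class",
            "matched", "offset", "window", "truncated",
        ],
    )


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in reports."""
    if total == 0:
        return 0.0
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def frequency_table(
    segments: Sequence[AnnotatedSegment], window: int = WINDOW
) -> pd.DataFrame:
    """Per-dataset RBS motif class frequencies.

    One row per ``dataset_label`` with sequence/ORF counts, motif-bearing
    ORF counts per class, and percentages of all annotated ORFs (half-up,
    one decimal). The 4/5/6-mer counts sum to ``n_with_motif`` by
    construction of the exclusive longest-class rule.
    """
    hits = scan_segments(segments, window=window)
    labels: dict[str, dict] = {}
    for seg in segments:
        row = labels.setdefault(
            seg.dataset_label,
            {"n_sequences": 0, "n_orfs": 0, "6-mer": 0, "5-mer": 0,
             "4-mer": 0, "none": 0},
        )
        row["n_sequences"] += 1
        row["n_orfs"] += len(seg.orfs)
    if not hits.empty:
        for (label, cls), n in (
            hits.groupby(["dataset_label", "motif_class"]).size().items()
        ):
            labels[label][cls] += n

    rows = []
    for label in sorted(labels):
        r = labels[label]
        if r["n_orfs"] == 0:
            warnings.warn(f"dataset {label!r} has no annotated ORFs")
        total = r["6-mer"] + r["5-mer"] + r["4-mer"]
        rows.append(
            {
                "dataset_label": label,
                "n_sequences": r["n_sequences"],
                "n_orfs": r["n_orfs"],
                "n_with_motif": total,
                "pct_with_motif": _pct(total, r["n_orfs"]),
                "n_4mer": r["4-mer"],
                "pct_4mer": _pct(r["4-mer"], r["n_orfs"]),
                "n_5mer": r["5-mer"],
                "pct_5mer": _pct(r["5-mer"], r["n_orfs"]),
                "n_6mer": r["6-mer"],
                "pct_6mer": _pct(r["6-mer"], r["n_orfs"]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------


def read_genbank(path, dataset_label: str = "") -> list[AnnotatedSegment]:
    """Read segments from a GenBank flat file; CDS features define ORFs."""
    from Bio import SeqIO

    segments = []
    for rec in SeqIO.parse(str(path), "genbank"):
        orfs = []
        n = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            qual = feat.qualifiers
            orf_id = (
                qual.get("locus_tag", qual.get("gene", [f"{rec.id}_cds{n}"]))
            )[0]
            orfs.append(
                ORF(
                    orf_id=orf_id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand=feat.location.strand or 1,
                )
            )
        segments.append(
            AnnotatedSegment(
                segment_id=rec.id,
                sequence=str(rec.seq),
                orfs=orfs,
                dataset_label=dataset_label or rec.annotations.get(
                    "source", ""
                ),
            )
        )
    return segments


def read_fasta_gff3(
    fasta_path, gff3_path, dataset_label: str = ""
) -> list[AnnotatedSegment]:
    """Read segments from FASTA plus GFF3 (``CDS`` features define ORFs)."""
    from Bio import SeqIO

    seqs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    orfs_by_seq: dict[str, list[ORF]] = {sid: [] for sid in seqs}
    counter: dict[str, int] = {}
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line[:60]!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype != "CDS":
                continue
            if seqid not in seqs:
                raise KeyError(f"GFF3 references unknown sequence {seqid!r}")
            counter[seqid] = counter.get(seqid, 0) + 1
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            orf_id = attr_map.get(
                "ID", f"{seqid}_cds{counter[seqid]}"
            )
            orfs_by_seq[seqid].append(
                ORF(
                    orf_id=orf_id,
                    start=int(start) - 1,  # GFF3 is 1-based inclusive
                    end=int(end),
                    strand=-1 if strand == "-" else 1,
                )
            )
    return [
        AnnotatedSegment(
            segment_id=sid,
            sequence=seq,
            orfs=orfs_by_seq[sid],
            dataset_label=dataset_label,
        )
        for sid, seq in seqs.items()
    ]


def write_genbank(segments: Sequence[AnnotatedSegment], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    records = []
    for seg in segments:
        rec = SeqRecord(
            Seq(seg.sequence),
            id=seg.segment_id,
            name=seg.segment_id[:16],
            description=seg.dataset_label,
            annotations={"molecule_type": "RNA"},
        )
        for orf in seg.orfs:
            rec.features.append(
                SeqFeature(
                    FeatureLocation(orf.start, orf.end, strand=orf.strand),
                    type="CDS",
                    qualifiers={"locus_tag": [orf.orf_id]},
                )
            )
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_fasta_gff3(
    segments: Sequence[AnnotatedSegment], fasta_path, gff3_path
) -> None:
    with open(fasta_path, "w") as fa:
        for seg in segments:
            fa.write(f">{seg.segment_id}\n")
            for i in range(0, len(seg.sequence), 70):
                fa.write(seg.sequence[i : i + 70] + "\n")
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for seg in segments:
            for orf in seg.orfs:
                gff.write(
                    "\t".join(
                        [
                            seg.segment_id,
                            "picobirnatax",
                            "CDS",
                            str(orf.start + 1),
                            str(orf.end),
                            ".",
                            "-" if orf.strand < 0 else "+",
                            "0",
                            f"ID={orf.orf_id}",
                        ]
                    )
                    + "\n"
                )
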