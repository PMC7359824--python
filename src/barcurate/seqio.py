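"""Sequence and metadata IO, quality control, and library assembly.

Barcode records are aligned COI fragments with a nominal taxon label and
an optional locality.  Quality control follows standard barcode-library
practice: a record must keep at least ``min_length`` ungapped bases and
must have at least one forward reading frame free of stop codons under
the vertebrate mitochondrial code.  Failing records are flagged, never
silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from barcurate.partition import Partition

logger = logging.getLogger(__name__)

IUPAC_CODES = set("ACGTRYSWKMBDHVN-")

#: NCBI translation table 2 (vertebrate mitochondrial).
VERTEBRATE_MITO = 2

__all__ = [
    "BarcodeRecord",
    "ReferenceLibrary",
    "load_library",
    "qc_filter",
    "trim_alignment",
    "write_outputs",
]


@dataclass
class BarcodeRecord:
    """One barcode sequence plus specimen metadata and QC status."""

    record_id: str
    sequence: str
    nominal_taxon: str = ""
    locality: str = ""
    qc_pass: bool = True
    qc_reasons: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")


@dataclass
class ReferenceLibrary:
    """Ordered collection of barcode records sharing one alignment frame."""

    records: List[BarcodeRecord]
    alignment_length: Optional[int] = None
    partition: Optional[Partition] = None

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r}")
        if self.alignment_length is None:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) == 1:
                self.alignment_length = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> List[str]:
        return [r.record_id for r in self.records]

    def get(self, record_id: str) -> BarcodeRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    def qc_passing(self) -> List[BarcodeRecord]:
        return [r for r in self.records if r.qc_pass]


def load_library(fasta_path, metadata_path=None) -> ReferenceLibrary:
    """Read a FASTA file (plus optional TSV metadata) into a library.

    The metadata TSV must be tab-separated with a header row containing at
    least ``record_id``, ``nominal_taxon`` and ``locality``; extra columns
    are ignored with a warning.  Every metadata id must occur in the FASTA.
    Records keep file order; sequences are uppercased.
    """
    fasta_path = Path(fasta_path)
    seen: Dict[str, str] = {}
    order: List[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {fasta_path}")
        seen[rec.id] = str(rec.seq).upper()
        order.append(rec.id)
    if not order:
        raise ValueError(f"no sequences found in {fasta_path}")

    meta: Dict[str, Dict[str, str]] = {}
    if metadata_path is not None:
        df = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
        required = {"record_id", "nominal_taxon", "locality"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns {sorted(missing)}")
        extra = set(df.columns) - required
        if extra:
            logger.warning("ignoring extra metadata columns: %s", sorted(extra))
        for row in df.itertuples(index=False):
            rid = row.record_id
            if rid not in seen:
                raise ValueError(f"metadata id {rid!r} absent from FASTA")
            meta[rid] = {
                "nominal_taxon": row.nominal_taxon,
                "locality": row.locality,
            }

    records = [
        BarcodeRecord(
            record_id=rid,
            sequence=seen[rid],
            nominal_taxon=meta.get(rid, {}).get("nominal_taxon", ""),
            locality=meta.get(rid, {}).get("locality", ""),
        )
        for rid in order
    ]
    return ReferenceLibrary(records=records)


def _min_stop_count(sequence: str, table_id: int) -> int:
    """Smallest number of stop codons over the three forward frames.

    Codons containing gaps or ambiguity codes are skipped: a stop codon
    must be unambiguous to count.
    """
    stops = set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    seq = sequence.replace("-", "")
    best = None
    for frame in range(3):
        n = 0
        for i in range(frame, len(seq) - 2, 3):
            if seq[i : i + 3] in stops:
                n += 1
        best = n if best is None else min(best, n)
    return 0 if best is None else best


def qc_filter(
    library: ReferenceLibrary,
    min_length: int = 500,
    genetic_code: int = VERTEBRATE_MITO,
) -> ReferenceLibrary:
    """Flag records shorter than ``min_length`` ungapped bases or with stop
    codons in every forward reading frame.  Idempotent; returns a new
    library, all records retained."""
    if not library.records:
        raise ValueError("cannot QC-filter an empty library")
    out = []
    for rec in library.records:
        reasons = []
        if rec.ungapped_length() < min_length:
            reasons.append("short")
        if _min_stop_count(rec.sequence, genetic_code) > 0:
            reasons.append("stop_codon")
        out.append(replace(rec, qc_pass=not reasons, qc_reasons=reasons))
    return ReferenceLibrary(
        records=out,
        alignment_length=library.alignment_length,
        partition=library.partition,
    )


def trim_alignment(library: ReferenceLibrary, start: int, end: int) -> ReferenceLibrary:
    """Slice all sequences to the 0-based half-open window [start, end)."""
    if not (0 <= start < end):
        raise ValueError(f"invalid trim window [{start}, {end})")
    shortest = min(len(r.sequence) for r in library.records)
    if end > shortest:
        raise ValueError(
            f"trim end {end} beyond shortest aligned length {shortest}"
        )
    out = [replace(r, sequence=r.sequence[start:end]) for r in library.records]
    return ReferenceLibrary(
        records=out, alignment_length=end - start, partition=library.partition
    )


def write_outputs(
    library: ReferenceLibrary,
    partition: Optional[Partition],
    outcomes: Sequence,
    out_dir,
) -> Dict[str, Path]:
    """Write the library (FASTA), metadata + OTU + QC table (TSV), per-query
    assignment outcomes (TSV), and a run summary (JSON) to ``out_dir``.

    ``load_library`` on the written FASTA/TSV round-trips ids, sequences
    and metadata fields losslessly.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}")

    paths = {
        "fasta": out_dir / "sequences.fasta",
        "tsv": out_dir / "records.tsv",
        "outcomes": out_dir / "outcomes.tsv",
        "json": out_dir / "summary.json",
    }

    with open(paths["fasta"], "w") as fh:
        for rec in library.records:
            fh.write(f">{rec.record_id}\n{rec.sequence}\n")

    rows = []
    for rec in library.records:
        rows.append(
            {
                "record_id": rec.record_id,
                "nominal_taxon": rec.nominal_taxon,
                "locality": rec.locality,
                "otu_id": partition.assignments.get(rec.record_id, "")
                if partition
                else "",
                "qc_pass": rec.qc_pass,
                "qc_reasons": ";".join(rec.qc_reasons),
            }
        )
    pd.DataFrame(rows).to_csv(paths["tsv"], sep="\t", index=False)

    orows = []
    for oc in outcomes:
        for method, entry in oc.entries.items():
            orows.append(
                {
                    "query_id": oc.query_id,
                    "method": method,
                    "selected_otu": entry.selected_otu,
                    "probability": round(entry.probability, 2),
                    "dist_to_selected": entry.dist_to_selected,
                    "nn_otu": entry.nn_otu,
                    "dist_to_nn": entry.dist_to_nn,
                    "ratio": entry.ratio,
                }
            )
        orows.append(
            {
                "query_id": oc.query_id,
                "method": "consensus",
                "selected_otu": oc.consensus_otu,
                "probability": round(oc.mean_probability, 2),
                "dist_to_selected": "",
                "nn_otu": "",
                "dist_to_nn": "",
                "ratio": "",
            }
        )
    pd.DataFrame(
        orows,
        columns=[
            "query_id",
            "method",
            "selected_otu",
            "probability",
            "dist_to_selected",
            "nn_otu",
            "dist_to_nn",
            "ratio",
        ],
    ).to_csv(paths["outcomes"], sep="\t", index=False)

    summary = {
        "n_records": len(library.records),
        "n_qc_pass": sum(r.qc_pass for r in library.records),
        "n_otus": partition.n_otus() if partition else 0,
        "n_outcomes": len(outcomes),
    }
    with open(paths["json"], "w") as fh:
        json.dump(summary, fh, indent=2)
    return paths
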