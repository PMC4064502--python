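"""FASTA sequence dumps and TSV statistic tables.

FASTA headers are ``rep<r>|gen<t>|ind<id>|<sex>|<class><locus_index>|copy<k>``
with 70-column line wrapping; files are written atomically (temp + rename) and
re-readable by any standard FASTA parser.  The statistics table is one row per
(replicate, generation, locus) with the fixed column schema below.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, List, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .sequence import PackedSequence, decode_words, encode
from .stats import SequencePanel, SummaryStats

__all__ = ["STATS_COLUMNS", "read_fasta", "stats_row", "write_fasta", "write_stats"]

STATS_COLUMNS = [
    "replicate", "generation", "locus_class", "locus_index",
    "n", "L", "S", "theta_w", "pi", "h", "H_A", "H_N",
]

FASTA_WRAP = 70


def stats_row(replicate: int, generation: int, locus_class, locus_index: int,
              stats: SummaryStats) -> dict:
    return {
        "replicate": replicate,
        "generation": generation,
        "locus_class": locus_class.value,
        "locus_index": locus_index,
        "n": stats.n,
        "L": stats.L,
        "S": stats.S,
        "theta_w": stats.theta_w,
        "pi": stats.pi,
        "h": stats.h,
        "H_A": stats.H_A,
        "H_N": stats.H_N,
    }


def _atomic_handle(path: str):
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    return os.fdopen(fd, "w"), tmp


def write_stats(rows: Iterable[dict], path: str) -> None:
    """Write statistic rows as a TSV with a header line (decimal dot, no
    locale formatting)."""
    rows = list(rows)
    if not rows:
        raise ValueError("no statistic rows to write")
    frame = pd.DataFrame(rows, columns=STATS_COLUMNS)
    handle, tmp = _atomic_handle(path)
    try:
        with handle:
            frame.to_csv(handle, sep="\t", index=False, lineterminator="\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_fasta(panels: Iterable[SequencePanel], path: str) -> None:
    """Dump every sequence of every panel as one FASTA record."""
    panels = list(panels)
    if not panels:
        raise ValueError("no panels to write")
    records = []
    for panel in panels:
        for k in range(panel.n):
            header = (
                f"rep{panel.replicate}|gen{panel.generation}|"
                f"ind{int(panel.individual_ids[k])}|{panel.sexes[k]}|"
                f"{panel.locus_class.value}{panel.locus_index}|"
                f"copy{int(panel.copy_slots[k])}"
            )
            records.append(
                SeqRecord(Seq(decode_words(panel.words[k], panel.length)),
                          id=header, description="")
            )
    handle, tmp = _atomic_handle(path)
    try:
        with handle:
            writer = FastaWriter(handle, wrap=FASTA_WRAP)
            writer.write_file(records)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fasta(path: str) -> List[Tuple[str, PackedSequence]]:
    """Read a FASTA file back as (header, PackedSequence) pairs."""
    out = []
    for record in SeqIO.parse(path, "fasta"):
        out.append((record.id, encode(str(record.seq))))
    return out
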