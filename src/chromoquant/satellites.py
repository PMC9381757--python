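"""Alignment-free major-satellite assays on FASTQ files.

Mouse pericentromeric heterochromatin is built of major-satellite tandem
repeats.  Rather than mapping reads to a repeat-masked genome (which biases
against repeats), these assays scan raw FASTQ records for eight diagnostic
satellite subsequences — four motifs and their reverse complements — and
report:

* the fraction of reads carrying any motif (a proxy for satellite
  enrichment in e.g. ChIP-seq libraries), and
* for whole-genome bisulfite libraries, the percentage of C residues within
  motif occurrences that read as T (bisulfite conversion; its complement
  proxies satellite DNA methylation).

Both operations stream the file in constant memory and work on plain or
gzip-compressed FASTQ.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SATELLITE_MOTIFS",
    "SatelliteAssayResult",
    "count_satellite_reads",
    "bisulfite_conversion",
    "reverse_complement",
]

# The eight diagnostic major-satellite subsequences. Motifs 5-8 are the
# reverse complements of motifs 1-4 (verified below), so the set is closed
# under strand flips and reads from either strand are counted.
SATELLITE_MOTIFS: tuple[str, ...] = (
    "GACGACTTGAAAAATGACGAAATC",
    "CATATTCCAGGTCCTTCAGTGTGC",
    "GAAAAAGGTGGAAAATTTAGA",
    "AGAAAACTGAAAATCATGGAAAAT",
    "GATTTCGTCATTTTTCAAGTCGTC",
    "GCACACTGAAGGACCTGGAATATG",
    "TCTAAATTTTCCACCTTTTTC",
    "ATTTTCCATGATTTTCAGTTTTCT",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motifs(motifs: tuple[str, ...]) -> None:
    if len(motifs) != 8:
        raise ValueError(f"expected 8 motifs, got {len(motifs)}")
    for m in motifs:
        if not m or set(m) - set("ACGT"):
            raise ValueError(f"motif {m!r} is not an uppercase DNA string")
    for i, j in ((0, 4), (1, 5), (2, 6), (3, 7)):
        if reverse_complement(motifs[i]) != motifs[j]:
            raise ValueError(
                f"motif set is not reverse-complement closed: "
                f"rc(motifs[{i}]) != motifs[{j}]"
            )


_validate_motifs(SATELLITE_MOTIFS)

# Bisulfite conversion turns unmethylated C into T, so a converted motif
# occurrence differs from the reference motif only at C positions. Matching
# uses motif variants with every C wildcarded to [CT]; all other positions
# stay exact. C positions of each motif are tallied per occurrence.
_C_POSITIONS: tuple[tuple[int, ...], ...] = tuple(
    tuple(i for i, b in enumerate(m) if b == "C") for m in SATELLITE_MOTIFS
)
# Lookahead makes overlapping occurrences visible.
_WILDCARD_PATTERNS: tuple[re.Pattern, ...] = tuple(
    re.compile("(?=" + "".join("[CT]" if b == "C" else b for b in m) + ")")
    for m in SATELLITE_MOTIFS
)


class FastqFormatError(ValueError):
    """Malformed FASTQ record, reported with its 1-based record number."""


@dataclass
class SatelliteAssayResult:
    """Counts and percentages from one FASTQ satellite assay.

    ``percent_satellite`` is 100 * satellite reads / total reads; in
    bisulfite mode ``percent_conversion`` is 100 * converted / assayed motif
    C sites.  Percentages are ``None`` when their denominator is zero
    (``empty`` / no assayed sites), never silently 0.
    """

    source: str
    n_reads_total: int
    n_satellite_reads: int
    percent_satellite: float | None = None
    bisulfite: bool = False
    n_c_sites_assayed: int = 0
    n_converted: int = 0
    percent_conversion: float | None = None
    empty: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.n_satellite_reads > self.n_reads_total:
            raise ValueError("satellite reads exceed total reads")
        self.empty = self.n_reads_total == 0
        if not self.empty:
            self.percent_satellite = 100.0 * self.n_satellite_reads / self.n_reads_total
        if self.bisulfite and self.n_c_sites_assayed > 0:
            self.percent_conversion = 100.0 * self.n_converted / self.n_c_sites_assayed

    def to_row(self) -> dict:
        return {
            "source": self.source,
            "n_reads_total": self.n_reads_total,
            "n_satellite_reads": self.n_satellite_reads,
            "percent_satellite": self.percent_satellite,
            "bisulfite": self.bisulfite,
            "n_c_sites_assayed": self.n_c_sites_assayed,
            "n_converted": self.n_converted,
            "percent_conversion": self.percent_conversion,
        }


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_sequences(fastq_path):
    """Yield uppercase read sequences; wrap parse errors with record numbers.

    Streams plain or gzipped FASTQ in constant memory; a malformed record
    aborts with its 1-based record number rather than being skipped.
    """
    n = 0
    try:
        with _open_text(fastq_path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                n += 1
                if not seq:
                    raise FastqFormatError(f"record {n} has an empty sequence")
                yield seq.upper()
    except FastqFormatError:
        raise
    except Exception as exc:
        raise FastqFormatError(
            f"malformed FASTQ {fastq_path} at or after record {n + 1}: {exc}"
        ) from exc


def count_satellite_reads(
    fastq_path, motifs: tuple[str, ...] = SATELLITE_MOTIFS
) -> SatelliteAssayResult:
    """Count reads containing any satellite motif as an exact substring.

    Matching is case-insensitive and literal (no mismatches — a mismatch
    allowance would be a different assay); a read is counted at most once
    however many motifs it contains.  Reads shorter than a motif simply
    cannot match it.
    """
    _validate_motifs(motifs)
    n_total = n_sat = 0
    for seq in _iter_sequences(fastq_path):
        n_total += 1
        if any(m in seq for m in motifs):
            n_sat += 1
    return SatelliteAssayResult(
        source=str(Path(fastq_path)), n_reads_total=n_total, n_satellite_reads=n_sat
    )


def bisulfite_conversion(
    fastq_path, motifs: tuple[str, ...] = SATELLITE_MOTIFS
) -> SatelliteAssayResult:
    """Estimate percent bisulfite conversion at satellite-motif C residues.

    Reads are matched against C-wildcarded motif variants (each motif C may
    read C or T; every other position exact).  Each matched occurrence
    contributes one assayed site per motif C position, tallied converted if
    the read shows T there and unconverted if C.  Overlapping occurrences of
    different motifs on one read are each tallied; motifs without C
    positions can match but contribute no assayed sites.
    """
    _validate_motifs(motifs)
    if motifs is SATELLITE_MOTIFS:
        patterns, c_positions = _WILDCARD_PATTERNS, _C_POSITIONS
    else:
        patterns = tuple(
            re.compile("(?=" + "".join("[CT]" if b == "C" else b for b in m) + ")")
            for m in motifs
        )
        c_positions = tuple(tuple(i for i, b in enumerate(m) if b == "C") for m in motifs)

    n_total = n_sat = n_sites = n_conv = 0
    for seq in _iter_sequences(fastq_path):
        n_total += 1
        matched = False
        for pat, cpos in zip(patterns, c_positions):
            for m in pat.finditer(seq):
                matched = True
                start = m.start()
                for j in cpos:
                    n_sites += 1
                    if seq[start + j] == "T":
                        n_conv += 1
        n_sat += matched
    return SatelliteAssayResult(
        source=str(Path(fastq_path)),
        n_reads_total=n_total,
        n_satellite_reads=n_sat,
        bisulfite=True,
        n_c_sites_assayed=n_sites,
        n_converted=n_conv,
    )
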