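"""Read-to-strain assignment and the strain x sample count matrix.

Reads are fixed-structure amplicons, so barcodes are extracted positionally
(template offsets) and matched by Hamming distance of the concatenated
24-nt barcode against every library pair; the unique pair within
``max_mismatch`` wins, ties are ambiguous, everything else is unassigned.
An optional offset scan (+-k nt) handles ragged 5' ends in real data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .barcodes import AmpliconTemplate, BarcodeLibrary, BARCODE_LENGTH, BASES

UNASSIGNED = "__unassigned__"
AMBIGUOUS = "__ambiguous__"


@dataclass
class CountMatrix:
    """Non-negative integer strain x sample counts with read accounting.

    Per sample, assigned + unassigned + ambiguous equals the number of reads
    processed.  ``counts`` rows are strains, columns samples.
    """

    counts: pd.DataFrame
    unassigned: pd.Series | None = None
    ambiguous: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (
            not np.issubdtype(arr.dtype, np.integer) or (arr < 0).any()
        ):
            raise ValueError("counts must be non-negative integers")
        if self.unassigned is None:
            self.unassigned = pd.Series(0, index=self.counts.columns)
        if self.ambiguous is None:
            self.ambiguous = pd.Series(0, index=self.counts.columns)
        for name, s in (("unassigned", self.unassigned), ("ambiguous", self.ambiguous)):
            if not s.index.equals(self.counts.columns):
                raise ValueError(f"{name} tally index must match sample columns")
            if (s < 0).any():
                raise ValueError(f"{name} tallies must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def strains(self) -> list[str]:
        return list(self.counts.index)

    def library_sizes(self) -> pd.Series:
        """Total assigned reads per sample (excludes unassigned/ambiguous)."""
        return self.counts.sum(axis=0)

    def total_reads(self) -> pd.Series:
        return self.library_sizes() + self.unassigned + self.ambiguous

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.loc[UNASSIGNED] = self.unassigned
        out.loc[AMBIGUOUS] = self.ambiguous
        out.index.name = "strain_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.astype(np.int64)
        unassigned = (
            df.loc[UNASSIGNED] if UNASSIGNED in df.index else None
        )
        ambiguous = df.loc[AMBIGUOUS] if AMBIGUOUS in df.index else None
        df = df.drop(index=[r for r in (UNASSIGNED, AMBIGUOUS) if r in df.index])
        return cls(df, unassigned=unassigned, ambiguous=ambiguous)


_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def _encode(seq: str) -> np.ndarray | None:
    """Encode ACGT to int8 indices; None if the sequence has other characters."""
    try:
        return np.array([_BASE_IDX[c] for c in seq], dtype=np.int8)
    except KeyError:
        return None


@dataclass
class _Matcher:
    """Precomputed 24-nt pair codes for vectorized Hamming matching."""

    library: BarcodeLibrary
    template: AmpliconTemplate
    codes: np.ndarray = field(init=False)  # (n_pairs, 24)
    ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.ids = self.library.strain_ids
        self.codes = np.stack(
            [
                _encode(up + dn)
                for up, dn in self.library.pairs.values()
            ]
        )

    def extract(self, seq: str, shift: int = 0) -> np.ndarray | None:
        """The concatenated 24-nt barcode at template offsets (+shift)."""
        t = self.template
        a, b = t.offset_up + shift, t.offset_dn + shift
        if a < 0 or b + BARCODE_LENGTH > len(seq):
            return None
        window = seq[a : a + BARCODE_LENGTH] + seq[b : b + BARCODE_LENGTH]
        return _encode(window)

    def match_one(self, barcode24: np.ndarray) -> tuple[int, int]:
        """(best index, best distance); index -1 on a tie at the minimum."""
        d = (self.codes != barcode24).sum(axis=1)
        best = int(d.argmin())
        dmin = int(d[best])
        if (d == dmin).sum() > 1:
            return -1, dmin
        return best, dmin


def match_read(
    read: str,
    library: BarcodeLibrary,
    template: AmpliconTemplate | None = None,
    max_mismatch: int = 1,
    offset_scan: int = 0,
    _matcher: _Matcher | None = None,
) -> tuple[str | None, str]:
    """Assign one read; returns (strain_id or None, status).

    Status is one of ``assigned``, ``ambiguous``, ``unassigned``.  Reads
    shorter than the template span are unassigned, not fatal.  With
    ``offset_scan=k`` the template offsets are additionally tried at shifts
    -k..k and the best-scoring shift wins (ties at the minimum distance
    across shifts and pairs are ambiguous).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if _matcher is None:
        _matcher = _Matcher(library, template or AmpliconTemplate())
    read = read.upper()
    best_d = None
    best_idx: int | None = None
    tie = False
    for shift in range(-offset_scan, offset_scan + 1):
        code = _matcher.extract(read, shift)
        if code is None:
            continue
        idx, d = _matcher.match_one(code)
        if best_d is None or d < best_d:
            best_d, best_idx, tie = d, idx, idx == -1
        elif d == best_d and idx != best_idx:
            tie = True
    if best_d is None or best_d > max_mismatch:
        return None, "unassigned"
    if tie or best_idx == -1:
        return None, "ambiguous"
    return _matcher.ids[best_idx], "assigned"


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_reads(source) -> "iter":
    """Yield read sequences from FASTQ path(s) or an iterable of sequences.

    A string made only of IUPAC base characters is treated as a read
    sequence; anything else is a file path.
    """
    if isinstance(source, (str, Path)):
        source = [source]
    for item in source:
        is_seq = isinstance(item, str) and bool(item) and all(
            c in "ACGTNacgtn" for c in item
        ) and not Path(item).exists()
        if is_seq:
            yield item
        elif isinstance(item, (str, Path)):
            if not Path(str(item)).exists():
                raise FileNotFoundError(f"FASTQ file not found: {item}")
            with _open_maybe_gzip(item) as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    yield str(rec.seq)
        else:
            yield str(item)


def count_samples(
    fastq_paths: dict[str, object],
    library: BarcodeLibrary,
    template: AmpliconTemplate | None = None,
    max_mismatch: int = 1,
    offset_scan: int = 0,
) -> CountMatrix:
    """Stream per-sample FASTQ files into a strain x sample CountMatrix.

    ``fastq_paths`` maps sample id -> FASTQ path, list of paths (counts from
    multiple files for one sample add), or an in-memory iterable of read
    sequences.  Every strain in the library appears as a row (zero-filled
    where unobserved); read accounting (assigned + unassigned + ambiguous =
    reads processed) holds per sample.  Output is independent of read order.
    """
    template = template or AmpliconTemplate()
    matcher = _Matcher(library, template)
    samples = list(fastq_paths)
    if len(set(samples)) != len(samples):
        raise ValueError("sample ids must be unique")
    counts = pd.DataFrame(0, index=library.strain_ids, columns=samples, dtype=np.int64)
    unassigned = pd.Series(0, index=samples, dtype=np.int64)
    ambiguous = pd.Series(0, index=samples, dtype=np.int64)
    for sample, source in fastq_paths.items():
        n_reads = 0
        for seq in _iter_reads(source):
            n_reads += 1
            sid, status = match_read(
                seq,
                library,
                template,
                max_mismatch=max_mismatch,
                offset_scan=offset_scan,
                _matcher=matcher,
            )
            if status == "assigned":
                counts.loc[sid, sample] += 1
            elif status == "ambiguous":
                ambiguous[sample] += 1
            else:
                unassigned[sample] += 1
        if n_reads == 0:
            import warnings

            warnings.warn(f"sample {sample!r}: no reads; zero column emitted")
    return CountMatrix(counts, unassigned=unassigned, ambiguous=ambiguous)
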