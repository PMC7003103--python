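"""Bipartite barcode libraries and the amplicon template.

Each strain is tagged by a pair of 12-nt barcodes flanking a fixed 92-nt
loxP-scar spacer.  Strain identity is the *pair*, so k up-codes and m
dn-codes address up to k*m strains (e.g. 96 strains from 20 primer pairs'
worth of codes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BARCODE_LENGTH = 12

#: Fixed 92-nt loxP-scar spacer used by the simulator (any fixed sequence of
#: the correct length works; only its length and constancy matter).
DEFAULT_SPACER = (
    "AATTATGTGTAGAATTTCACTAATACTTCAACGGCGTTGCATGCTCATTAC"
    "AAACTACCGCTATAGTGAACGCGCGATTGGCATCAATTTTC"
)

#: Fixed downstream priming context used to pad reads to full length.
DEFAULT_FLANK_DN = "GGTCGGTATAATTGGGTAGCGCGGAGGTTGGTAT"


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AmpliconTemplate:
    """Layout of the 150-bp single-end barcode amplicon read.

    The read is ``flank_up + barcode_up + spacer + barcode_dn`` padded with
    ``flank_dn`` context up to ``read_length``.  With the default empty
    upstream flank (primers trimmed upstream) the up-barcode occupies
    positions 1-12, the spacer 13-104 and the dn-barcode 105-116 (1-based).
    """

    spacer: str = DEFAULT_SPACER
    flank_up: str = ""
    flank_dn: str = DEFAULT_FLANK_DN
    read_length: int = 150

    def __post_init__(self) -> None:
        span = len(self.flank_up) + 2 * BARCODE_LENGTH + len(self.spacer)
        if span > self.read_length:
            raise ValueError(
                f"amplicon span {span} exceeds read length {self.read_length}"
            )
        for name in ("spacer", "flank_up", "flank_dn"):
            seq = getattr(self, name)
            if any(c not in BASES for c in seq):
                raise ValueError(f"{name} contains non-ACGT characters")

    @property
    def offset_up(self) -> int:
        """0-based offset of the up-barcode within the read."""
        return len(self.flank_up)

    @property
    def offset_dn(self) -> int:
        """0-based offset of the dn-barcode within the read."""
        return self.offset_up + BARCODE_LENGTH + len(self.spacer)

    @property
    def span(self) -> int:
        """Minimum read length needed to extract both barcodes."""
        return self.offset_dn + BARCODE_LENGTH


@dataclass
class BarcodeLibrary:
    """Ordered mapping strain_id -> (barcode_up, barcode_dn).

    Pairs must be unique; individual codes may repeat (combinatorial
    indexing).  Codes are uppercase ACGT of length 12.
    """

    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for sid, (up, dn) in self.pairs.items():
            for code in (up, dn):
                if len(code) != BARCODE_LENGTH:
                    raise ValueError(
                        f"strain {sid!r}: barcode {code!r} is not "
                        f"{BARCODE_LENGTH} nt"
                    )
                if any(c not in BASES for c in code):
                    raise ValueError(f"strain {sid!r}: non-ACGT barcode {code!r}")
            if (up, dn) in seen:
                raise ValueError(f"duplicate barcode pair for strain {sid!r}")
            seen.add((up, dn))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, strain_id: str) -> bool:
        return strain_id in self.pairs

    @property
    def strain_ids(self) -> list[str]:
        return list(self.pairs)

    def min_pairwise_distances(self) -> tuple[int, int]:
        """Minimum Hamming distance among distinct up-codes and dn-codes.

        Returns (min_up, min_dn); a position is BARCODE_LENGTH+1 sentinel
        when fewer than two distinct codes exist on that side.
        """
        out = []
        for idx in (0, 1):
            codes = sorted({p[idx] for p in self.pairs.values()})
            if len(codes) < 2:
                out.append(BARCODE_LENGTH + 1)
            else:
                out.append(
                    min(hamming(a, b) for a, b in itertools.combinations(codes, 2))
                )
        return out[0], out[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(sid, up, dn) for sid, (up, dn) in self.pairs.items()],
            columns=["strain_id", "barcode_up", "barcode_dn"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class InfeasibleLibraryError(ValueError):
    """Raised when the requested library cannot be constructed."""


def _sample_codes(
    n_codes: int, min_distance: int, rng: np.random.Generator, max_tries: int
) -> list[str]:
    """Rejection-sample 12-nt codes with pairwise Hamming >= min_distance."""
    codes: list[str] = []
    tries = 0
    while len(codes) < n_codes:
        if tries >= max_tries:
            raise InfeasibleLibraryError(
                f"could not place {n_codes} codes at min Hamming distance "
                f"{min_distance} after {max_tries} attempts"
            )
        tries += 1
        cand = "".join(BASES[i] for i in rng.integers(0, 4, BARCODE_LENGTH))
        if all(hamming(cand, c) >= min_distance for c in codes):
            codes.append(cand)
    return codes


def make_barcode_library(
    n_strains: int,
    min_distance: int = 3,
    seed: int = 0,
    n_up: int | None = None,
    n_dn: int | None = None,
    strain_ids: list[str] | None = None,
) -> BarcodeLibrary:
    """Build a combinatorial library of ``n_strains`` unique barcode pairs.

    Up- and dn-codes are drawn independently so that every pair of distinct
    codes on each side differs in at least ``min_distance`` positions; strains
    are assigned pairs combinatorially (row-major over up x dn), so
    ``n_up * n_dn >= n_strains`` codes suffice.  Deterministic given ``seed``.

    Raises
    ------
    InfeasibleLibraryError
        If the requested distance cannot be met (never silently relaxed).
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if min_distance < 1 or min_distance > BARCODE_LENGTH:
        raise InfeasibleLibraryError(
            f"min_distance must be in [1, {BARCODE_LENGTH}]"
        )
    if n_up is None:
        n_up = int(np.ceil(np.sqrt(n_strains)))
    if n_dn is None:
        n_dn = int(np.ceil(n_strains / n_up))
    if n_up * n_dn < n_strains:
        raise InfeasibleLibraryError(
            f"{n_up} x {n_dn} codes address only {n_up * n_dn} strains"
        )
    rng = np.random.default_rng(seed)
    max_tries = 2000 * (n_up + n_dn)
    ups = _sample_codes(n_up, min_distance, rng, max_tries)
    dns = _sample_codes(n_dn, min_distance, rng, max_tries)
    if strain_ids is None:
        width = max(3, len(str(n_strains)))
        strain_ids = [f"S{i + 1:0{width}d}" for i in range(n_strains)]
    elif len(strain_ids) != n_strains:
        raise ValueError("strain_ids length must equal n_strains")
    pairs = {
        sid: (ups[k // n_dn], dns[k % n_dn]) for k, sid in enumerate(strain_ids)
    }
    return BarcodeLibrary(pairs)


def load_barcode_library(path) -> BarcodeLibrary:
    """Load a 3-column TSV (strain_id, barcode_up, barcode_dn).

    A header row is detected by non-ACGT content in columns 2-3.  Malformed
    rows fail with their 1-based row number.
    """
    pairs: dict[str, tuple[str, str]] = {}
    seen_pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}: row {row_no}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            sid, up, dn = (f.strip() for f in fields)
            if row_no == 1 and any(
                c not in "ACGTN" for c in (up + dn).upper()
            ):
                continue  # header row (labels, not sequence-like content)
            for code in (up, dn):
                if len(code) != BARCODE_LENGTH:
                    raise ValueError(
                        f"{path}: row {row_no}: barcode {code!r} is not "
                        f"{BARCODE_LENGTH} nt"
                    )
                if any(c not in BASES for c in code):
                    raise ValueError(
                        f"{path}: row {row_no}: non-ACGT barcode {code!r}"
                    )
            if sid in pairs:
                raise ValueError(f"{path}: row {row_no}: duplicate strain id {sid!r}")
            if (up, dn) in seen_pairs:
                raise ValueError(
                    f"{path}: row {row_no}: duplicate barcode pair ({up}, {dn})"
                )
            pairs[sid] = (up, dn)
            seen_pairs.add((up, dn))
    if not pairs:
        raise ValueError(f"{path}: no barcode records found")
    return BarcodeLibrary(pairs)
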