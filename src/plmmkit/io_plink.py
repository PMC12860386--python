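"""Reading and writing PLINK 1 binary filesets and delimited feature matrices.

The central container is :class:`GenotypeMatrix`: an ``n_samples x n_features``
dosage matrix (allele counts in {0, 1, 2}, ``NaN`` for missing) together with
sample and feature identifiers.  Continuous features (e.g. gene expression read
from a CSV) live in the same container; nothing downstream assumes integer
dosages.

Storage is either in memory or *filebacked*: the matrix is written once to a
flat binary file of float64 values in column-major (feature-major) order with a
JSON sidecar describing shape and identifiers, and accessed thereafter through
a read-only memory map.  Column-block access against the memory map is the
access pattern of standardization, relatedness accumulation and coordinate
descent, so data larger than memory never need to be fully resident.

PLINK 1 ``.bed`` layout (SNP-major): three header bytes ``0x6C 0x1B 0x01``
followed by one record per variant of ``ceil(n/4)`` bytes.  Each byte packs
four samples, two bits each, least-significant pair first; the 2-bit codes are
``00`` = 2 copies of A1, ``10`` = 1 copy, ``11`` = 0 copies, ``01`` = missing.
Trailing pad bits in the last byte of a record are ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    FormatError,
    IntegrityError,
    UnsupportedLayoutError,
)

_BED_MAGIC = (0x6C, 0x1B)
_SNP_MAJOR = 0x01

# code -> A1 allele count; 0b01 is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _byte_decode_table() -> np.ndarray:
    """(256, 4) lookup: byte value -> dosages of its four samples, LSB pair first."""
    table = np.empty((256, 4))
    for b in range(256):
        for k in range(4):
            table[b, k] = _CODE_TO_DOSAGE[(b >> (2 * k)) & 0b11]
    return table


_DECODE_LUT = _byte_decode_table()


@dataclass
class GenotypeMatrix:
    """Samples x features dosage matrix with identifiers and missingness.

    ``dosages`` is float64 with ``NaN`` marking missing entries; it may be a
    read-only ``np.memmap`` when ``storage_mode == "filebacked"``.
    """

    dosages: np.ndarray
    sample_ids: list[tuple[str, str]]
    feature_ids: list[str]
    storage_mode: str = "in_memory"
    backing_path: Path | None = None
    sample_groups: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise IntegrityError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.feature_ids) != p:
            raise IntegrityError(
                f"{len(self.feature_ids)} feature ids for {p} dosage columns"
            )
        if len(set(self.feature_ids)) != p:
            raise IntegrityError("feature_ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_features(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(np.asarray(self.dosages))

    def column_block(self, start: int, stop: int) -> np.ndarray:
        """Materialize columns ``start:stop`` as an in-memory array."""
        return np.array(self.dosages[:, start:stop])

    def iter_column_blocks(self, chunk: int) -> Iterator[tuple[int, np.ndarray]]:
        for j0 in range(0, self.n_features, max(int(chunk), 1)):
            j1 = min(j0 + chunk, self.n_features)
            yield j0, self.column_block(j0, j1)

    def to_filebacked(self, backing_path: str | Path, chunk_features: int = 1024) -> "GenotypeMatrix":
        """Write the matrix once to a flat binary + JSON sidecar, return a mapped view."""
        backing_path = Path(backing_path)
        n, p = self.dosages.shape
        mm = np.memmap(backing_path, dtype=np.float64, mode="w+", shape=(n, p), order="F")
        for j0, block in self.iter_column_blocks(chunk_features):
            mm[:, j0 : j0 + block.shape[1]] = block
        mm.flush()
        del mm
        sidecar = {
            "shape": [n, p],
            "dtype": "float64",
            "order": "F",
            "sample_ids": [list(s) for s in self.sample_ids],
            "feature_ids": list(self.feature_ids),
        }
        backing_path.with_suffix(backing_path.suffix + ".json").write_text(
            json.dumps(sidecar)
        )
        return open_filebacked(backing_path)


def open_filebacked(backing_path: str | Path) -> GenotypeMatrix:
    """Open a previously written backing file as a memory-mapped GenotypeMatrix."""
    backing_path = Path(backing_path)
    sidecar_path = backing_path.with_suffix(backing_path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    n, p = meta["shape"]
    mm = np.memmap(backing_path, dtype=np.float64, mode="r", shape=(n, p), order="F")
    return GenotypeMatrix(
        dosages=mm,
        sample_ids=[tuple(s) for s in meta["sample_ids"]],
        feature_ids=list(meta["feature_ids"]),
        storage_mode="filebacked",
        backing_path=backing_path,
    )


def _resolve_prefix(bed_path: str | Path) -> Path:
    p = Path(bed_path)
    return p.with_suffix("") if p.suffix == ".bed" else p


def read_plink(
    bed_path: str | Path,
    filebacked: bool = False,
    backing_path: str | Path | None = None,
    chunk_features: int = 1024,
    count_allele: str = "A1",
) -> GenotypeMatrix:
    """Decode a PLINK 1 ``.bed/.bim/.fam`` fileset into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    bed_path
        Path to the ``.bed`` file or the shared fileset prefix.
    filebacked
        Write the decoded matrix to ``backing_path`` (default: prefix +
        ``.fbm``) and return a memory-mapped view instead of an in-memory array.
    chunk_features
        Number of variants decoded per chunk in filebacked mode.
    count_allele
        ``"A1"`` (default) counts A1 alleles (code ``00`` → 2); ``"A2"`` flips
        the orientation.  Orientation only flips coefficient signs downstream.
    """
    if count_allele not in ("A1", "A2"):
        raise ValueError("count_allele must be 'A1' or 'A2'")
    prefix = _resolve_prefix(bed_path)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"missing PLINK file {f}")

    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    sample_ids = list(zip(fam_df[0], fam_df[1]))
    n = len(sample_ids)
    if bim.stat().st_size == 0:
        feature_ids: list[str] = []
    else:
        bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
        feature_ids = list(bim_df[1])
    p = len(feature_ids)

    with open(bed, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3:
            raise FormatError(f"{bed}: truncated header ({len(header)} bytes)")
        if header[0] != _BED_MAGIC[0] or header[1] != _BED_MAGIC[1]:
            bad = 0 if header[0] != _BED_MAGIC[0] else 1
            raise FormatError(
                f"{bed}: bad magic byte {bad}: got {header[bad]:#04x}, "
                f"expected {_BED_MAGIC[bad]:#04x}"
            )
        if header[2] == 0x00:
            raise UnsupportedLayoutError(
                f"{bed}: individual-major layout (mode byte 0x00) is not supported"
            )
        if header[2] != _SNP_MAJOR:
            raise FormatError(f"{bed}: unknown mode byte {header[2]:#04x}")

        bytes_per_variant = (n + 3) // 4
        expected = bytes_per_variant * p
        payload_size = bed.stat().st_size - 3
        if payload_size != expected:
            raise IntegrityError(
                f"{bed}: payload is {payload_size} bytes but .bim/.fam imply "
                f"{p} variants x {bytes_per_variant} bytes = {expected}"
            )

        def decode_rows(raw: bytes, n_variants: int) -> np.ndarray:
            rows = np.frombuffer(raw, dtype=np.uint8).reshape(n_variants, bytes_per_variant)
            vals = _DECODE_LUT[rows].reshape(n_variants, 4 * bytes_per_variant)[:, :n]
            return vals.T  # n x n_variants

        if not filebacked:
            raw = fh.read(expected)
            dosages = np.ascontiguousarray(decode_rows(raw, p)) if p else np.empty((n, 0))
            if count_allele == "A2":
                dosages = 2.0 - dosages
            return GenotypeMatrix(dosages, sample_ids, feature_ids)

        if backing_path is None:
            backing_path = prefix.with_suffix(".fbm")
        backing_path = Path(backing_path)
        mm = np.memmap(backing_path, dtype=np.float64, mode="w+", shape=(n, p), order="F")
        done = 0
        while done < p:
            take = min(chunk_features, p - done)
            raw = fh.read(take * bytes_per_variant)
            block = decode_rows(raw, take)
            if count_allele == "A2":
                block = 2.0 - block
            mm[:, done : done + take] = block
            done += take
        mm.flush()
        del mm

    sidecar = {
        "shape": [n, p],
        "dtype": "float64",
        "order": "F",
        "sample_ids": [list(s) for s in sample_ids],
        "feature_ids": feature_ids,
    }
    backing_path.with_suffix(backing_path.suffix + ".json").write_text(json.dumps(sidecar))
    return open_filebacked(backing_path)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Emit a PLINK 1 fileset (``prefix``.bed/.bim/.fam) that ``read_plink`` inverts.

    Dosages must be in {0, 1, 2, missing}; unknown variant metadata is filled
    with defaults (chromosome 1, cM 0, bp = 1-based feature index, alleles
    A1="A", A2="B").
    """
    prefix = Path(prefix)
    n, p = g.dosages.shape
    dos = np.asarray(g.dosages, dtype=np.float64)
    finite = dos[np.isfinite(dos)]
    if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
        bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
        raise IntegrityError(f"non-integer dosage {bad!r}: .bed encodes only 0/1/2/missing")

    bytes_per_variant = (n + 3) // 4
    # map dosage -> 2-bit code; NaN -> 01
    codes = np.full((n, p), 0b01, dtype=np.uint8)
    for value, code in _DOSAGE_TO_CODE.items():
        codes[dos == value] = code
    padded = np.zeros((4 * bytes_per_variant, p), dtype=np.uint8)
    padded[:n] = codes
    # pack 4 samples per byte, least-significant pair first
    quads = padded.reshape(bytes_per_variant, 4, p)
    packed = (
        quads[:, 0, :]
        | (quads[:, 1, :] << 2)
        | (quads[:, 2, :] << 4)
        | (quads[:, 3, :] << 6)
    ).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([_BED_MAGIC[0], _BED_MAGIC[1], _SNP_MAJOR]))
        fh.write(packed.T.tobytes())  # variant-major records

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, fid in enumerate(g.feature_ids):
            fh.write(f"1\t{fid}\t0\t{j + 1}\tA\tB\n")

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for famid, iid in g.sample_ids:
            fh.write(f"{famid}\t{iid}\t0\t0\t0\t-9\n")


def read_delimited(
    path: str | Path,
    id_column: str,
    delimiter: str | None = None,
) -> GenotypeMatrix:
    """Parse a rectangular delimited table (header row, one ID column) of features.

    Empty cells and ``NA`` become missing.  Values are not restricted to
    {0, 1, 2}: continuous features such as expression are accepted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed table: {exc}") from exc
    if id_column not in df.columns:
        raise AlignmentError(
            f"{path}: ID column {id_column!r} not found; "
            f"available columns: {list(df.columns)}"
        )
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise IntegrityError(f"{path}: duplicate sample ID {dup!r}")
    feat = df.drop(columns=[id_column])
    try:
        values = feat.astype(np.float64).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric feature values: {exc}") from exc
    sample_ids = [(s, s) for s in ids]
    return GenotypeMatrix(values, sample_ids, [str(c) for c in feat.columns])
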