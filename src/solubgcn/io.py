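"""Per-residue feature blocks: reading, validation, normalization and stacking.

A protein is described by up to six per-residue feature blocks, each an
``L x d`` real matrix (``L`` = sequence length):

====================  ====  =============================================
block                 d     content
====================  ====  =============================================
``ESM``               20    amino-acid output probabilities of a protein
                            language model, used zero-shot
``BLOSUM``            20    BLOSUM62 substitution row per residue
``AAPHY7``            7     physicochemical property values
``PSSM``              20    position-specific scoring matrix (evolutionary)
``HMM``               30    profile-HMM emission/transition features
``SPIDER3``           14    predicted structural properties
====================  ====  =============================================

Blocks are stacked column-wise in the canonical order above into the hybrid
feature ``H`` (``L x C``, ``C = sum of d``); the stacking order is fixed so
channel indices are reproducible regardless of the order files are read.

On-disk dialect: one tab-delimited matrix per protein per block
(``<id>.<block>.tsv``), one ``L x L`` contact-probability matrix
(``<id>.contact.tsv``), a FASTA of sequences, and a two-column TSV of
solubility labels.  A YAML/JSON manifest describes a dataset directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    AlignmentError,
    ConfigError,
    DataError,
    ParseError,
    ShapeError,
)

#: Canonical stacking order of the feature blocks.
BLOCK_ORDER: tuple[str, ...] = ("ESM", "BLOSUM", "AAPHY7", "PSSM", "HMM", "SPIDER3")

#: Default per-block channel counts.
DEFAULT_BLOCK_DIMS: dict[str, int] = {
    "ESM": 20,
    "BLOSUM": 20,
    "AAPHY7": 7,
    "PSSM": 20,
    "HMM": 30,
    "SPIDER3": 14,
}

#: Lower-case aliases accepted on the command line.
BLOCK_ALIASES: dict[str, str] = {
    "esm": "ESM",
    "blosum": "BLOSUM",
    "aap": "AAPHY7",
    "aaphy7": "AAPHY7",
    "pssm": "PSSM",
    "hmm": "HMM",
    "spider": "SPIDER3",
    "spider3": "SPIDER3",
}

NORMALIZATION_SCHEMES = ("none", "minmax_per_channel", "zscore_per_channel")


def canonical_block_name(name: str) -> str:
    """Map a block name or alias to its canonical upper-case form."""
    if name in BLOCK_ORDER:
        return name
    key = name.lower()
    if key in BLOCK_ALIASES:
        return BLOCK_ALIASES[key]
    raise ConfigError(f"unknown feature block {name!r}; known: {BLOCK_ORDER}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureBlock:
    """One named ``L x d`` per-residue feature matrix."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.name = canonical_block_name(self.name)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ShapeError(
                f"block {self.name}: expected a 2-D matrix, got {self.matrix.ndim}-D"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ShapeError(f"block {self.name}: matrix contains non-finite entries")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


@dataclass
class HybridFeature:
    """The stacked hybrid feature ``H`` with named channel-block boundaries.

    ``block_spans`` maps each block name to its half-open channel interval
    ``[start, stop)``; the spans partition ``[0, C)`` in canonical order.
    """

    matrix: np.ndarray
    block_spans: dict[str, tuple[int, int]]

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def C(self) -> int:
        return self.matrix.shape[1]

    def block(self, name: str) -> np.ndarray:
        """Return the channel slice for one block (a view, not a copy)."""
        start, stop = self.block_spans[canonical_block_name(name)]
        return self.matrix[:, start:stop]


@dataclass
class ContactMap:
    """An ``L x L`` matrix of residue-residue contact probabilities."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"contact map must be square, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ShapeError("contact map contains non-finite entries")
        if m.size and (m.min() < -1e-9 or m.max() > 1 + 1e-9):
            raise ShapeError("contact probabilities must lie in [0, 1]")
        if m.size and np.abs(m - m.T).max() > 1e-6:
            raise ShapeError("contact map is not symmetric (tolerance 1e-6)")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ProteinRecord:
    """One protein: id, sequence, feature blocks, contact map, optional label."""

    id: str
    sequence: str
    blocks: dict[str, FeatureBlock] = field(default_factory=dict)
    contact: ContactMap | None = None
    solubility: float | None = None

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for blk in self.blocks.values():
            if blk.L != L:
                raise AlignmentError(
                    f"protein {self.id}: block {blk.name} has {blk.L} rows "
                    f"but sequence length is {L}"
                )
        if self.contact is not None and self.contact.L != L:
            raise AlignmentError(
                f"protein {self.id}: contact map is {self.contact.L}x{self.contact.L} "
                f"but sequence length is {L}"
            )
        if self.solubility is not None and not (0.0 <= self.solubility <= 1.0):
            raise ShapeError(
                f"protein {self.id}: solubility {self.solubility} outside [0, 1]"
            )

    @property
    def L(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# matrix file I/O
# ---------------------------------------------------------------------------


def _parse_matrix(path: Path) -> np.ndarray:
    """Parse a whitespace- or comma-delimited numeric matrix.

    Parse failures report the 1-based row and column of the offending cell.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.replace(",", " ").split()
            row: list[float] = []
            for j, cell in enumerate(cells, start=1):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                    ) from None
            if rows and len(row) != len(rows[0]):
                raise ParseError(
                    f"{path}: row {i} has {len(row)} columns, expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def load_feature_matrix(path: str | Path, name: str, expected_dim: int | None = None) -> FeatureBlock:
    """Load one per-residue feature block and validate its channel count.

    Parameters
    ----------
    path : file path of a tab/space/comma-delimited numeric matrix, no header.
    name : block name (canonical or alias).
    expected_dim : declared channel count; defaults to the block's standard
        dimension.  A mismatch raises :class:`ShapeError` naming the block and
        the found-vs-expected dimensions.
    """
    path = Path(path)
    name = canonical_block_name(name)
    if expected_dim is None:
        expected_dim = DEFAULT_BLOCK_DIMS[name]
    matrix = _parse_matrix(path)
    if matrix.shape[1] != expected_dim:
        raise ShapeError(
            f"{path}: block {name} has {matrix.shape[1]} channels, "
            f"expected {expected_dim}"
        )
    return FeatureBlock(name=name, matrix=matrix)


def write_feature_matrix(path: str | Path, matrix: np.ndarray, fmt: str = "%.8g") -> None:
    """Write a matrix in the tab-delimited dialect read by the loaders."""
    np.savetxt(path, np.atleast_2d(np.asarray(matrix, dtype=float)), fmt=fmt, delimiter="\t")


def load_contact_map(path: str | Path) -> ContactMap:
    """Load an ``L x L`` contact-probability matrix."""
    return ContactMap(matrix=_parse_matrix(Path(path)))


# ---------------------------------------------------------------------------
# stacking and normalization
# ---------------------------------------------------------------------------


def stack_features(blocks: Iterable[FeatureBlock]) -> HybridFeature:
    """Column-stack feature blocks into the hybrid feature ``H``.

    Blocks are reordered into the canonical order regardless of input order.
    All blocks must agree on ``L``; duplicate block names are rejected.
    """
    by_name: dict[str, FeatureBlock] = {}
    for blk in blocks:
        if blk.name in by_name:
            raise ShapeError(f"duplicate feature block {blk.name!r}")
        by_name[blk.name] = blk
    if not by_name:
        raise ConfigError("stack_features requires at least one block")
    ordered = [by_name[n] for n in BLOCK_ORDER if n in by_name]
    L = ordered[0].L
    for blk in ordered:
        if blk.L != L:
            raise AlignmentError(
                f"block {blk.name} has {blk.L} rows but block "
                f"{ordered[0].name} has {L}"
            )
    spans: dict[str, tuple[int, int]] = {}
    start = 0
    for blk in ordered:
        spans[blk.name] = (start, start + blk.d)
        start += blk.d
    matrix = np.concatenate([blk.matrix for blk in ordered], axis=1)
    return HybridFeature(matrix=matrix, block_spans=spans)


class ChannelNormalizer:
    """Per-channel normalization with statistics frozen on the training set.

    ``minmax_per_channel`` affinely maps each channel's training min/max to
    ``[0, 1]``; held-out values may fall outside that interval and are not
    clipped.  ``zscore_per_channel`` centres and scales to unit training
    standard deviation.  Constant channels map to zero under both schemes.
    """

    def __init__(self, scheme: str = "minmax_per_channel"):
        if scheme not in NORMALIZATION_SCHEMES:
            raise ConfigError(
                f"unknown normalization scheme {scheme!r}; "
                f"known: {NORMALIZATION_SCHEMES}"
            )
        self.scheme = scheme
        self.center_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, matrices: Sequence[np.ndarray] | np.ndarray) -> "ChannelNormalizer":
        if isinstance(matrices, np.ndarray):
            stacked = matrices
        else:
            stacked = np.vstack(list(matrices))
        if self.scheme == "none":
            self.center_ = np.zeros(stacked.shape[1])
            self.scale_ = np.ones(stacked.shape[1])
        elif self.scheme == "minmax_per_channel":
            lo = stacked.min(axis=0)
            hi = stacked.max(axis=0)
            rng = hi - lo
            self.center_ = lo
            self.scale_ = np.where(rng > 0, rng, 1.0)
            self._degenerate = rng == 0
        else:  # zscore_per_channel
            mu = stacked.mean(axis=0)
            sd = stacked.std(axis=0)
            self.center_ = mu
            self.scale_ = np.where(sd > 0, sd, 1.0)
            self._degenerate = sd == 0
        if self.scheme == "none":
            self._degenerate = np.zeros(stacked.shape[1], dtype=bool)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.center_ is None:
            raise ConfigError("ChannelNormalizer used before fit()")
        out = (np.asarray(matrix, dtype=float) - self.center_) / self.scale_
        if self._degenerate.any():
            out[:, self._degenerate] = 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "degenerate": self._degenerate.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelNormalizer":
        obj = cls(scheme=d["scheme"])
        obj.center_ = np.asarray(d["center"], dtype=float)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        obj._degenerate = np.asarray(d["degenerate"], dtype=bool)
        return obj


def normalize_block(
    block: FeatureBlock,
    scheme: str,
    normalizer: ChannelNormalizer | None = None,
) -> FeatureBlock:
    """Normalize one block per channel.

    When ``normalizer`` is given its (training-set) statistics are applied;
    otherwise statistics are computed from the block itself.  ``scheme='none'``
    returns the matrix bitwise-unchanged.
    """
    if scheme not in NORMALIZATION_SCHEMES:
        raise ConfigError(
            f"unknown normalization scheme {scheme!r}; known: {NORMALIZATION_SCHEMES}"
        )
    if scheme == "none":
        return FeatureBlock(name=block.name, matrix=block.matrix.copy())
    if normalizer is None:
        normalizer = ChannelNormalizer(scheme).fit(block.matrix)
    elif normalizer.scheme != scheme:
        raise ConfigError(
            f"normalizer was fitted with scheme {normalizer.scheme!r}, got {scheme!r}"
        )
    return FeatureBlock(name=block.name, matrix=normalizer.transform(block.matrix))


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def load_labels(path: str | Path) -> pd.Series:
    """Load the two-column ``id<TAB>solubility`` label table (with header)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns with a header")
    series = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    bad = series[(series < 0) | (series > 1)]
    if len(bad):
        raise ShapeError(
            f"{path}: solubility outside [0, 1] for {', '.join(bad.index[:5])}"
        )
    return series


DEFAULT_MANIFEST = {
    "fasta": "proteins.fasta",
    "labels": "labels.tsv",
    "features_dir": "features",
    "contacts_dir": "contacts",
    "blocks": dict(DEFAULT_BLOCK_DIMS),
    "normalization": "minmax_per_channel",
    "contact_threshold": 0.0,
    "adjacency_normalization": "sym_degree",
}


def load_manifest(path: str | Path) -> dict:
    """Load a dataset manifest (YAML or JSON), filling in defaults."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    manifest = dict(DEFAULT_MANIFEST)
    manifest.update(data or {})
    manifest["blocks"] = {
        canonical_block_name(k): int(v) for k, v in manifest["blocks"].items()
    }
    return manifest


def load_dataset(
    directory: str | Path,
    manifest: Mapping | None = None,
    blocks: Sequence[str] | None = None,
    require_labels: bool = False,
) -> list[ProteinRecord]:
    """Load all proteins of a dataset directory.

    Missing block files for an enabled block are a hard error; blocks are
    disabled by configuration (``blocks=`` or the manifest), never silently by
    absence.
    """
    directory = Path(directory)
    if manifest is None:
        mpath = directory / "manifest.yaml"
        manifest = load_manifest(mpath) if mpath.exists() else dict(DEFAULT_MANIFEST)
    enabled = (
        [canonical_block_name(b) for b in blocks]
        if blocks is not None
        else [b for b in BLOCK_ORDER if b in manifest["blocks"]]
    )
    sequences = read_fasta(directory / manifest["fasta"])
    labels_path = directory / manifest["labels"]
    labels = load_labels(labels_path) if labels_path.exists() else pd.Series(dtype=float)
    fdir = directory / manifest["features_dir"]
    cdir = directory / manifest["contacts_dir"]

    records: list[ProteinRecord] = []
    for pid, seq in sequences.items():
        blks: dict[str, FeatureBlock] = {}
        for name in enabled:
            fpath = fdir / f"{pid}.{name}.tsv"
            if not fpath.exists():
                raise DataError(
                    f"protein {pid}: missing feature file for enabled block "
                    f"{name} ({fpath})"
                )
            blks[name] = load_feature_matrix(fpath, name, manifest["blocks"][name])
        cpath = cdir / f"{pid}.contact.tsv"
        if not cpath.exists():
            raise DataError(f"protein {pid}: missing contact map ({cpath})")
        sol = float(labels[pid]) if pid in labels.index else None
        if require_labels and sol is None:
            raise DataError(f"protein {pid}: missing solubility label")
        records.append(
            ProteinRecord(
                id=pid,
                sequence=seq,
                blocks=blks,
                contact=load_contact_map(cpath),
                solubility=sol,
            )
        )
    return records


def write_dataset(
    records: Sequence[ProteinRecord],
    directory: str | Path,
    manifest_extra: Mapping | None = None,
) -> Path:
    """Write records in the on-disk dialect (FASTA + TSV matrices + manifest)."""
    directory = Path(directory)
    (directory / "features").mkdir(parents=True, exist_ok=True)
    (directory / "contacts").mkdir(parents=True, exist_ok=True)
    write_fasta(directory / "proteins.fasta", {r.id: r.sequence for r in records})
    labeled = [(r.id, r.solubility) for r in records if r.solubility is not None]
    with open(directory / "labels.tsv", "w") as fh:
        fh.write("id\tsolubility\n")
        for pid, sol in labeled:
            fh.write(f"{pid}\t{sol:.6f}\n")
    block_dims: dict[str, int] = {}
    for rec in records:
        for name, blk in rec.blocks.items():
            block_dims[name] = blk.d
            write_feature_matrix(directory / "features" / f"{rec.id}.{name}.tsv", blk.matrix)
        if rec.contact is not None:
            write_feature_matrix(
                directory / "contacts" / f"{rec.id}.contact.tsv", rec.contact.matrix
            )
    manifest = dict(DEFAULT_MANIFEST)
    manifest["blocks"] = {b: block_dims[b] for b in BLOCK_ORDER if b in block_dims}
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory
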