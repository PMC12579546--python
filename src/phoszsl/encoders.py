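"""Fixed-length vector representations for phosphosite windows and kinase domains.

Two families of representations are supported:

* **Baseline encodings** computed directly from sequence: one-hot,
  BLOSUM62 rows, NLF-style physicochemical descriptors, and trigram
  (ProtVec-style) averages from a user-supplied table.  Fixed-length
  windows concatenate one block per position; variable-length domains are
  position-averaged into a single block.
* **Precomputed embeddings** produced upstream by protein language models
  and consumed here as files: either one vector per identifier, or a token
  matrix per identifier awaiting pooling (column-wise average over non-pad
  tokens, or the CLS summary token verbatim).

Kinase vectors can additionally be augmented with one-hot family/group
blocks and a multi-hot Enzyme Commission block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .dataset import (
    AA20,
    DEFAULT_PAD,
    KinaseRecord,
    PhosphositeRecord,
    PhoszslError,
    SENTINEL_FAMILY,
    SENTINEL_GROUP,
    SEQUENCE_ALPHABET,
)


class EncodingError(PhoszslError):
    """Sequence outside the encoder's alphabet, or missing constant table."""


#: Alphabet for window encodings: 20 residues + X + the pad character.
WINDOW_ALPHABET = SEQUENCE_ALPHABET + DEFAULT_PAD

#: Alphabet for domain encodings (no pad character occurs in domains).
DOMAIN_ALPHABET = SEQUENCE_ALPHABET


# ---------------------------------------------------------------------------
# Baseline sequence encodings
# ---------------------------------------------------------------------------


def one_hot_encode(
    seq: str, alphabet: str = WINDOW_ALPHABET, pooled: bool = False
) -> np.ndarray:
    """Binary indicator encoding of a sequence.

    ``pooled=False`` concatenates one indicator block per position
    (length ``len(seq) * len(alphabet)``); ``pooled=True`` averages the
    blocks into residue frequencies on the probability simplex.
    """
    if not seq:
        raise EncodingError("cannot encode an empty sequence")
    index = {c: i for i, c in enumerate(alphabet)}
    blocks = np.zeros((len(seq), len(alphabet)))
    for pos, c in enumerate(seq):
        if c not in index:
            raise EncodingError(f"character {c!r} outside alphabet {alphabet!r}")
        blocks[pos, index[c]] = 1.0
    return blocks.mean(axis=0) if pooled else blocks.ravel()


def _blosum62_rows() -> tuple[dict[str, np.ndarray], int]:
    mat = substitution_matrices.load("BLOSUM62")
    rows = {}
    for aa in SEQUENCE_ALPHABET:
        rows[aa] = np.array([float(mat[aa, b]) for b in AA20])
    return rows, len(AA20)


_BLOSUM_ROWS, _BLOSUM_DIM = _blosum62_rows()


def blosum62_encode(
    seq: str, pooled: bool = False, pad_char: str = DEFAULT_PAD
) -> np.ndarray:
    """Per-position BLOSUM62 substitution rows, concatenated or averaged.

    Each residue maps to its 20-entry row of the BLOSUM62 matrix; pad
    characters contribute zero rows.
    """
    return _table_encode(seq, _BLOSUM_ROWS, _BLOSUM_DIM, pooled, pad_char)


def _table_encode(
    seq: str,
    rows: Mapping[str, np.ndarray],
    dim: int,
    pooled: bool,
    pad_char: str,
) -> np.ndarray:
    if not seq:
        raise EncodingError("cannot encode an empty sequence")
    blocks = np.zeros((len(seq), dim))
    for pos, c in enumerate(seq):
        if c == pad_char:
            continue
        if c not in rows:
            raise EncodingError(f"character {c!r} has no row in the coefficient table")
        blocks[pos] = rows[c]
    return blocks.mean(axis=0) if pooled else blocks.ravel()


def load_nlf_table(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Load an NLF-style per-residue coefficient table.

    Without ``path`` this loads the packaged ``nlf_synthetic.tsv``: a
    synthetic stand-in (18 descriptors per residue derived from a spectral
    embedding of the BLOSUM62 similarity matrix) for the published
    non-linear-Fisher-transform table, which is distributed through an
    epitope-prediction tool rather than as a plain file.  Pass ``path`` to
    use the genuine coefficients.
    """
    if path is None:
        ref = resources.files("phoszsl").joinpath("data/nlf_synthetic.tsv")
        if not ref.is_file():
            raise EncodingError(
                "NLF coefficient table not found; supply one as TSV "
                "(residue column + one column per descriptor)"
            )
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return {str(aa): row.to_numpy(dtype=float) for aa, row in df.iterrows()}


def nlf_encode(
    seq: str,
    table: Mapping[str, np.ndarray] | None = None,
    pooled: bool = False,
    pad_char: str = DEFAULT_PAD,
) -> np.ndarray:
    """Per-position physicochemical descriptor rows (NLF-style).

    ``table`` maps residues to fixed-length descriptor rows; by default the
    packaged synthetic stand-in table is used (see :func:`load_nlf_table`).
    Pad characters and residues absent from the table (e.g. X) contribute
    zero rows.
    """
    if table is None:
        table = load_nlf_table()
    dims = {len(v) for v in table.values()}
    if len(dims) != 1:
        raise EncodingError("NLF table rows have inconsistent lengths")
    dim = dims.pop()
    rows = {aa: np.asarray(v, dtype=float) for aa, v in table.items()}
    core = {c: rows.get(c, np.zeros(dim)) for c in SEQUENCE_ALPHABET}
    return _table_encode(seq, core, dim, pooled, pad_char)


def protvec_encode(seq: str, trigram_table: Mapping[str, np.ndarray]) -> np.ndarray:
    """Mean of the vectors of all overlapping 3-grams of the sequence.

    Out-of-vocabulary 3-grams contribute a zero vector (they still count in
    the denominator).  Sequences shorter than 3 cannot be encoded.
    """
    if len(seq) < 3:
        raise EncodingError("sequence shorter than 3 has no 3-grams")
    dims = {len(v) for v in trigram_table.values()}
    if len(dims) != 1:
        raise EncodingError("trigram table rows have inconsistent lengths")
    dim = dims.pop()
    grams = [seq[i : i + 3] for i in range(len(seq) - 2)]
    acc = np.zeros(dim)
    for g in grams:
        vec = trigram_table.get(g)
        if vec is not None:
            acc += np.asarray(vec, dtype=float)
    return acc / len(grams)


def read_trigram_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a trigram vector table (TSV: 3-gram column + value columns)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return {str(g): row.to_numpy(dtype=float) for g, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Token pooling for precomputed embeddings
# ---------------------------------------------------------------------------


def pool_tokens(
    token_matrix: np.ndarray,
    pad_mask: np.ndarray | None = None,
    mode: str = "avg",
    cls_index: int = 0,
) -> np.ndarray:
    """Summarise an L x dim token matrix into a single vector.

    ``avg`` takes the column-wise mean over non-pad rows (``pad_mask`` is
    True at padding rows); ``cls`` returns the summary-token row verbatim.
    """
    matrix = np.asarray(token_matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise EncodingError("token matrix must be a non-empty 2-D array")
    if mode == "cls":
        return matrix[cls_index].copy()
    if mode != "avg":
        raise EncodingError(f"unknown pooling mode {mode!r}")
    if pad_mask is None:
        pad_mask = np.zeros(matrix.shape[0], dtype=bool)
    pad_mask = np.asarray(pad_mask, dtype=bool)
    if pad_mask.shape[0] != matrix.shape[0]:
        raise EncodingError("pad mask length does not match token matrix rows")
    keep = ~pad_mask
    if not keep.any():
        raise EncodingError("all token rows are masked; nothing to pool")
    return matrix[keep].mean(axis=0)


# ---------------------------------------------------------------------------
# Embedding stores
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingStore:
    """Identifier-keyed fixed-dimension vectors, optionally with token matrices."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    token_matrices: dict[str, np.ndarray] = field(default_factory=dict)
    pad_masks: dict[str, np.ndarray] = field(default_factory=dict)
    has_cls: bool = False

    def __post_init__(self) -> None:
        for key, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dim,):
                raise EncodingError(
                    f"vector {key!r} has shape {vec.shape}, expected ({self.dim},)"
                )
            self.vectors[key] = vec
        for key, matrix in self.token_matrices.items():
            mask = self.pad_masks.get(key)
            if mask is not None and len(mask) != matrix.shape[0]:
                raise EncodingError(
                    f"token matrix {key!r}: pad mask length {len(mask)} != "
                    f"rows {matrix.shape[0]}"
                )

    @classmethod
    def from_vectors(cls, vectors: Mapping[str, np.ndarray]) -> "EmbeddingStore":
        arrays = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
        dims = {v.shape[-1] for v in arrays.values()}
        if len(dims) != 1:
            raise EncodingError(f"inconsistent vector dimensions: {sorted(dims)}")
        return cls(dim=dims.pop(), vectors=arrays)

    def matrix(self, ids: Sequence[str]) -> np.ndarray:
        """Stack vectors for ``ids`` into a (len(ids), dim) array."""
        missing = [i for i in ids if i not in self.vectors]
        if missing:
            raise EncodingError(f"identifiers missing from store: {missing[:5]}")
        return np.stack([self.vectors[i] for i in ids])

    def pooled(self, mode: str = "avg", cls_index: int = 0) -> "EmbeddingStore":
        """Pool every token matrix into a vector store."""
        if not self.token_matrices:
            raise EncodingError("store holds no token matrices to pool")
        if mode == "cls" and not self.has_cls:
            raise EncodingError("store was written without a CLS row")
        vectors = {
            key: pool_tokens(matrix, self.pad_masks.get(key), mode, cls_index)
            for key, matrix in self.token_matrices.items()
        }
        return EmbeddingStore.from_vectors(vectors)

    # -- IO ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        ids = list(self.vectors)
        df = pd.DataFrame(
            self.matrix(ids), index=pd.Index(ids, name="id"),
            columns=[f"v{i}" for i in range(self.dim)],
        )
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingStore":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_vectors(
            {str(i): row.to_numpy(dtype=float) for i, row in df.iterrows()}
        )

    def to_hdf5(self, path: str | Path) -> None:
        """Write token matrices (plus pad masks and the CLS flag) to HDF5."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["dim"] = self.dim
            fh.attrs["has_cls"] = self.has_cls
            grp = fh.create_group("tokens")
            for key, matrix in self.token_matrices.items():
                g = grp.create_group(key)
                g.create_dataset("matrix", data=matrix)
                mask = self.pad_masks.get(
                    key, np.zeros(matrix.shape[0], dtype=bool)
                )
                g.create_dataset("pad_mask", data=np.asarray(mask, dtype=bool))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EmbeddingStore":
        import h5py

        with h5py.File(path, "r") as fh:
            dim = int(fh.attrs["dim"])
            has_cls = bool(fh.attrs["has_cls"])
            token_matrices = {}
            pad_masks = {}
            for key, g in fh["tokens"].items():
                token_matrices[key] = g["matrix"][()].astype(float)
                pad_masks[key] = g["pad_mask"][()].astype(bool)
        return cls(
            dim=dim,
            token_matrices=token_matrices,
            pad_masks=pad_masks,
            has_cls=has_cls,
        )


# ---------------------------------------------------------------------------
# Dataset-level encoding helpers
# ---------------------------------------------------------------------------

BASELINE_ENCODERS = ("onehot", "blosum62", "nlf")


def encode_sites(
    sites: Mapping[str, PhosphositeRecord],
    method: str = "onehot",
    nlf_table: Mapping[str, np.ndarray] | None = None,
    trigram_table: Mapping[str, np.ndarray] | None = None,
) -> EmbeddingStore:
    """Encode every site window into a fixed-length vector store.

    Windows are fixed-length, so baseline encodings concatenate one block
    per position.
    """
    vectors = {}
    for site_id, rec in sites.items():
        if method == "onehot":
            vec = one_hot_encode(rec.window, WINDOW_ALPHABET, pooled=False)
        elif method == "blosum62":
            vec = blosum62_encode(rec.window, pooled=False, pad_char=rec.pad_char)
        elif method == "nlf":
            vec = nlf_encode(rec.window, nlf_table, pooled=False, pad_char=rec.pad_char)
        elif method == "protvec":
            if trigram_table is None:
                raise EncodingError("protvec encoding requires a trigram table")
            vec = protvec_encode(rec.window.strip(rec.pad_char), trigram_table)
        else:
            raise EncodingError(f"unknown encoding method {method!r}")
        vectors[site_id] = vec
    return EmbeddingStore.from_vectors(vectors)


def encode_kinases(
    kinases: Mapping[str, KinaseRecord],
    method: str = "onehot",
    nlf_table: Mapping[str, np.ndarray] | None = None,
    trigram_table: Mapping[str, np.ndarray] | None = None,
) -> EmbeddingStore:
    """Encode every kinase domain into a fixed-length vector store.

    Domains vary in length, so baseline encodings are position-averaged.
    """
    vectors = {}
    for kid, rec in kinases.items():
        seq = rec.domain_sequence
        if method == "onehot":
            vec = one_hot_encode(seq, DOMAIN_ALPHABET, pooled=True)
        elif method == "blosum62":
            vec = blosum62_encode(seq, pooled=True)
        elif method == "nlf":
            vec = nlf_encode(seq, nlf_table, pooled=True)
        elif method == "protvec":
            if trigram_table is None:
                raise EncodingError("protvec encoding requires a trigram table")
            vec = protvec_encode(seq, trigram_table)
        else:
            raise EncodingError(f"unknown encoding method {method!r}")
        vectors[kid] = vec
    return EmbeddingStore.from_vectors(vectors)


# ---------------------------------------------------------------------------
# Kinase annotation augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationVocab:
    """Ordered label vocabularies for family/group/EC one-hot blocks."""

    families: tuple[str, ...]
    groups: tuple[str, ...]
    ec_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, labels in [
            ("families", self.families),
            ("groups", self.groups),
            ("ec_classes", self.ec_classes),
        ]:
            if len(set(labels)) != len(labels):
                raise EncodingError(f"duplicate labels in {name}")
        if SENTINEL_FAMILY not in self.families or SENTINEL_GROUP not in self.groups:
            raise EncodingError("sentinel family/group labels must be present")

    @classmethod
    def from_kinases(cls, kinases: Mapping[str, KinaseRecord]) -> "AnnotationVocab":
        families = {r.family for r in kinases.values()} | {SENTINEL_FAMILY}
        groups = {r.group for r in kinases.values()} | {SENTINEL_GROUP}
        ecs = set().union(*(r.ec_classes for r in kinases.values())) if kinases else set()
        return cls(
            families=tuple(sorted(families)),
            groups=tuple(sorted(groups)),
            ec_classes=tuple(sorted(ecs)),
        )


def augment_kinase_vector(
    vec: np.ndarray,
    record: KinaseRecord,
    vocab: AnnotationVocab,
    use_family: bool = False,
    use_group: bool = False,
    use_ec: bool = False,
) -> np.ndarray:
    """Append annotation one-hot blocks to a kinase embedding vector.

    Family and group blocks are one-hot (sentinels catch unresolvable
    labels); the EC block is multi-hot because a kinase may carry several
    EC numbers.  With all flags off the input is returned unchanged.
    """
    vec = np.asarray(vec, dtype=float)
    parts = [vec]
    if use_family:
        block = np.zeros(len(vocab.families))
        label = record.family if record.family in vocab.families else SENTINEL_FAMILY
        block[vocab.families.index(label)] = 1.0
        parts.append(block)
    if use_group:
        block = np.zeros(len(vocab.groups))
        label = record.group if record.group in vocab.groups else SENTINEL_GROUP
        block[vocab.groups.index(label)] = 1.0
        parts.append(block)
    if use_ec:
        block = np.zeros(len(vocab.ec_classes))
        for ec in record.ec_classes:
            if ec in vocab.ec_classes:
                block[vocab.ec_classes.index(ec)] = 1.0
        parts.append(block)
    if len(parts) == 1:
        return vec
    return np.concatenate(parts)


def augment_store(
    store: EmbeddingStore,
    kinases: Mapping[str, KinaseRecord],
    vocab: AnnotationVocab,
    use_family: bool = False,
    use_group: bool = False,
    use_ec: bool = False,
) -> EmbeddingStore:
    """Apply :func:`augment_kinase_vector` to every kinase in a store."""
    vectors = {
        kid: augment_kinase_vector(
            vec, kinases[kid], vocab, use_family, use_group, use_ec
        )
        for kid, vec in store.vectors.items()
        if kid in kinases
    }
    return EmbeddingStore.from_vectors(vectors)
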