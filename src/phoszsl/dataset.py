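"""Domain types and readers/writers for kinase and phosphosite tables.

The data model mirrors how kinase-substrate resources distribute their
associations: a kinase table (domain sequence plus group/family/EC
annotations), a phosphosite table (one row per site, with the 15-mer
sequence window centred on the phosphorylated residue), and a pair table
listing which kinase phosphorylates which site.  A site may be paired with
several kinases, which makes downstream prediction a multilabel ranking
problem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: The 20 canonical amino acids, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in sequences: canonical plus the ambiguity code X.
SEQUENCE_ALPHABET = AA20 + "X"

#: Default padding character for windows truncated at a protein terminus.
DEFAULT_PAD = "_"

#: Window half-width: seven residues flanking the site on each side.
DEFAULT_FLANK = 7

#: Sentinel labels for kinases that cannot be assigned a group/family.
SENTINEL_GROUP = "Other2"
SENTINEL_FAMILY = "otherFamily"

#: Residues that can carry a phosphate group.
PHOSPHO_RESIDUES = frozenset("STY")


class PhoszslError(Exception):
    """Base class for all errors raised by this package."""


class DatasetError(PhoszslError):
    """Malformed or inconsistent dataset input."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinaseRecord:
    """One kinase: its domain sequence and categorical annotations.

    The kinase is the class label of the prediction task; ``group`` and
    ``family`` follow the usual kinome taxonomy and fall back to the
    sentinels ``Other2`` / ``otherFamily`` when unassignable.  ``ec_classes``
    may hold several Enzyme Commission numbers, or none.
    """

    kinase_id: str
    domain_sequence: str
    group: str = SENTINEL_GROUP
    family: str = SENTINEL_FAMILY
    ec_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.kinase_id:
            raise DatasetError("kinase_id must be non-empty")
        if not self.domain_sequence:
            raise DatasetError(f"kinase {self.kinase_id!r}: empty domain sequence")
        bad = set(self.domain_sequence) - set(SEQUENCE_ALPHABET)
        if bad:
            raise DatasetError(
                f"kinase {self.kinase_id!r}: invalid residues {sorted(bad)!r}"
            )
        if not self.group or not self.family:
            raise DatasetError(
                f"kinase {self.kinase_id!r}: group/family must be non-null "
                f"(use {SENTINEL_GROUP!r}/{SENTINEL_FAMILY!r} for unassigned)"
            )
        object.__setattr__(self, "ec_classes", frozenset(self.ec_classes))


@dataclass(frozen=True)
class PhosphositeRecord:
    """One phosphosite: a S/T/Y residue with its sequence window.

    ``position`` is 1-based on the substrate.  The window has length
    ``2 * flank + 1`` (15 by default) with the site at the centre; positions
    beyond a protein terminus are filled with a pad character, which may
    appear only as a contiguous prefix and/or suffix.
    """

    site_id: str
    substrate_id: str
    position: int
    residue: str
    window: str
    pad_char: str = DEFAULT_PAD

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DatasetError(f"site {self.site_id!r}: position must be >= 1")
        if self.residue not in PHOSPHO_RESIDUES:
            raise DatasetError(
                f"site {self.site_id!r}: residue {self.residue!r} is not S/T/Y"
            )
        w = self.window
        if len(w) % 2 == 0 or len(w) < 1:
            raise DatasetError(
                f"site {self.site_id!r}: window length {len(w)} is not odd"
            )
        centre = len(w) // 2
        if w[centre] != self.residue:
            raise DatasetError(
                f"site {self.site_id!r}: window centre {w[centre]!r} does not "
                f"match residue {self.residue!r}"
            )
        core = w.strip(self.pad_char)
        if self.pad_char in core:
            raise DatasetError(
                f"site {self.site_id!r}: pad characters must be contiguous at "
                "the window edges"
            )
        bad = set(core) - set(SEQUENCE_ALPHABET)
        if bad:
            raise DatasetError(
                f"site {self.site_id!r}: invalid residues {sorted(bad)!r}"
            )

    @classmethod
    def from_sequence(
        cls,
        substrate_id: str,
        sequence: str,
        position: int,
        flank: int = DEFAULT_FLANK,
        pad_char: str = DEFAULT_PAD,
    ) -> "PhosphositeRecord":
        """Build a record by extracting the window from a full sequence."""
        window = extract_window(sequence, position, flank=flank, pad_char=pad_char)
        return cls(
            site_id=f"{substrate_id}_{position}",
            substrate_id=substrate_id,
            position=position,
            residue=sequence[position - 1],
            window=window,
            pad_char=pad_char,
        )


def extract_window(
    sequence: str,
    position: int,
    flank: int = DEFAULT_FLANK,
    pad_char: str = DEFAULT_PAD,
) -> str:
    """Extract the sequence window centred on a 1-based position.

    The result always has length ``2 * flank + 1``; positions falling
    outside the sequence are filled with ``pad_char`` so the site stays
    centred even near the N or C terminus.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not 1 <= position <= len(sequence):
        raise DatasetError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    i = position - 1
    left = sequence[max(0, i - flank) : i]
    right = sequence[i + 1 : i + 1 + flank]
    return (
        pad_char * (flank - len(left))
        + left
        + sequence[i]
        + right
        + pad_char * (flank - len(right))
    )


# ---------------------------------------------------------------------------
# Association table and dataset container
# ---------------------------------------------------------------------------


class AssociationTable:
    """Ordered list of (site_id, kinase_id) pairs with a derived label map.

    Input order is preserved; duplicates are rejected.  ``site_labels``
    maps each site to the set of its kinases (the multilabel ground truth).
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: list[tuple[str, str]] = [(s, k) for s, k in pairs]
        seen: set[tuple[str, str]] = set()
        labels: dict[str, set[str]] = {}
        for pair in self.pairs:
            if pair in seen:
                raise DatasetError(f"duplicate pair {pair!r}")
            seen.add(pair)
            labels.setdefault(pair[0], set()).add(pair[1])
        self.site_labels: dict[str, set[str]] = labels

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AssociationTable) and self.pairs == other.pairs

    @property
    def site_ids(self) -> list[str]:
        """Distinct site ids in order of first appearance."""
        seen: set[str] = set()
        out = []
        for s, _ in self.pairs:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    @property
    def kinase_ids(self) -> list[str]:
        """Distinct kinase ids in order of first appearance."""
        seen: set[str] = set()
        out = []
        for _, k in self.pairs:
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def pair_counts(self) -> dict[str, int]:
        """Number of pairs per kinase."""
        counts: dict[str, int] = {}
        for _, k in self.pairs:
            counts[k] = counts.get(k, 0) + 1
        return counts

    def restrict_to_kinases(self, kinase_ids: Iterable[str]) -> "AssociationTable":
        """Sub-table of pairs whose kinase lies in ``kinase_ids``, order kept."""
        allowed = set(kinase_ids)
        return AssociationTable(p for p in self.pairs if p[1] in allowed)


@dataclass
class Dataset:
    """A kinase table, a site table and their association pairs."""

    kinases: dict[str, KinaseRecord]
    sites: dict[str, PhosphositeRecord]
    table: AssociationTable

    def __iter__(self):  # allow tuple-unpacking: kinases, sites, table
        return iter((self.kinases, self.sites, self.table))

    def validate(self) -> None:
        """Check every pair resolves to a known kinase and site."""
        for row, (site_id, kinase_id) in enumerate(self.table.pairs):
            if kinase_id not in self.kinases:
                raise DatasetError(
                    f"pair row {row}: unknown kinase {kinase_id!r} "
                    f"(site {site_id!r})"
                )
            if site_id not in self.sites:
                raise DatasetError(
                    f"pair row {row}: unknown site {site_id!r} "
                    f"(kinase {kinase_id!r})"
                )


# ---------------------------------------------------------------------------
# TSV / FASTA readers and writers
# ---------------------------------------------------------------------------

KINASE_COLUMNS = ["kinase_id", "domain_sequence", "group", "family", "ec"]
SITE_COLUMNS = ["site_id", "substrate_id", "position", "residue", "window"]
PAIR_COLUMNS = ["site_id", "kinase_id"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")
    return df


def read_kinases(path: str | Path) -> dict[str, KinaseRecord]:
    """Read a kinase TSV (kinase_id, domain_sequence, group, family, ec)."""
    df = _read_tsv(path, KINASE_COLUMNS)
    records: dict[str, KinaseRecord] = {}
    for row in df.itertuples(index=False):
        if row.kinase_id in records:
            raise DatasetError(f"{path}: duplicate kinase_id {row.kinase_id!r}")
        ec = frozenset(x for x in str(row.ec).split(",") if x)
        records[row.kinase_id] = KinaseRecord(
            kinase_id=row.kinase_id,
            domain_sequence=row.domain_sequence,
            group=row.group,
            family=row.family,
            ec_classes=ec,
        )
    return records


def read_sites(path: str | Path, pad_char: str = DEFAULT_PAD) -> dict[str, PhosphositeRecord]:
    """Read a phosphosite TSV (site_id, substrate_id, position, residue, window)."""
    df = _read_tsv(path, SITE_COLUMNS)
    records: dict[str, PhosphositeRecord] = {}
    for row in df.itertuples(index=False):
        if row.site_id in records:
            raise DatasetError(f"{path}: duplicate site_id {row.site_id!r}")
        records[row.site_id] = PhosphositeRecord(
            site_id=row.site_id,
            substrate_id=row.substrate_id,
            position=int(row.position),
            residue=row.residue,
            window=row.window,
            pad_char=pad_char,
        )
    return records


def read_pairs(path: str | Path) -> AssociationTable:
    """Read a pair TSV (site_id, kinase_id), preserving row order."""
    df = _read_tsv(path, PAIR_COLUMNS)
    return AssociationTable(
        (row.site_id, row.kinase_id) for row in df.itertuples(index=False)
    )


def read_dataset(
    kinase_path: str | Path,
    site_path: str | Path,
    pairs_path: str | Path,
    pad_char: str = DEFAULT_PAD,
) -> Dataset:
    """Read and cross-validate the three dataset tables."""
    ds = Dataset(
        kinases=read_kinases(kinase_path),
        sites=read_sites(site_path, pad_char=pad_char),
        table=read_pairs(pairs_path),
    )
    ds.validate()
    return ds


def write_kinases(records: Mapping[str, KinaseRecord], path: str | Path) -> None:
    rows = [
        {
            "kinase_id": r.kinase_id,
            "domain_sequence": r.domain_sequence,
            "group": r.group,
            "family": r.family,
            "ec": ",".join(sorted(r.ec_classes)),
        }
        for r in records.values()
    ]
    pd.DataFrame(rows, columns=KINASE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_sites(records: Mapping[str, PhosphositeRecord], path: str | Path) -> None:
    rows = [
        {
            "site_id": r.site_id,
            "substrate_id": r.substrate_id,
            "position": r.position,
            "residue": r.residue,
            "window": r.window,
        }
        for r in records.values()
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_pairs(table: AssociationTable, path: str | Path) -> None:
    pd.DataFrame(table.pairs, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def write_dataset(ds: Dataset, directory: str | Path) -> None:
    """Write kinases.tsv, sites.tsv and pairs.tsv into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_kinases(ds.kinases, directory / "kinases.tsv")
    write_sites(ds.sites, directory / "sites.tsv")
    write_pairs(ds.table, directory / "pairs.tsv")


def load_dataset_dir(directory: str | Path, pad_char: str = DEFAULT_PAD) -> Dataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    return read_dataset(
        directory / "kinases.tsv",
        directory / "sites.tsv",
        directory / "pairs.tsv",
        pad_char=pad_char,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read substrate sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def sites_from_fasta(
    fasta_path: str | Path,
    positions: Iterable[tuple[str, int]],
    flank: int = DEFAULT_FLANK,
    pad_char: str = DEFAULT_PAD,
) -> dict[str, PhosphositeRecord]:
    """Build phosphosite records from full substrate sequences.

    ``positions`` lists (substrate_id, 1-based position) tuples; windows are
    extracted with terminal padding.
    """
    seqs = read_fasta(fasta_path)
    records: dict[str, PhosphositeRecord] = {}
    for substrate_id, position in positions:
        if substrate_id not in seqs:
            raise DatasetError(f"substrate {substrate_id!r} not found in FASTA")
        rec = PhosphositeRecord.from_sequence(
            substrate_id, seqs[substrate_id], position, flank=flank, pad_char=pad_char
        )
        records[rec.site_id] = rec
    return records
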