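"""Readers, validators and identification-level filters for TMT quantification data.

This module owns every external file format the pipeline consumes:

* per-plex protein quantification tables (PEAKS-style ``proteins.csv`` dialect,
  one reporter-intensity column per TMT channel),
* the channel design table mapping (plex, channel) to biological sample
  coordinates and bridge status,
* a proteome FASTA with UniProt-style headers,
* GMT gene-set files and accession→gene mapping tables,
* PSM modification tables for TMT labeling QC.

Empty or zero reporter intensities are stored as missing values (``NaN``) and
never treated as zero downstream: a zero reporter intensity is censoring, not
evidence of absence.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import fasta as _pfasta
from pyteomics import mass as _pmass

from .exceptions import (
    ConfigurationError,
    FormatError,
    UndefinedStatisticError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues tolerated in FASTA sequences but excluded from mass computation.
DEFAULT_EXTRA_RESIDUES = frozenset("UXBZ")

METADATA_COLUMNS = ("gene", "description", "n_peptides", "n_unique_peptides")


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantDialect:
    """Column-name profile of a protein quantification export.

    The default matches a PEAKS X ``proteins.csv`` export.  Reporter-intensity
    columns are discovered with ``intensity_pattern`` (the ``channel`` group
    becomes the channel label) unless an explicit ``channel_columns`` mapping
    of channel label → column name is supplied.  Unknown extra columns are
    ignored.
    """

    accession: str = "Accession"
    description: str = "Description"
    n_peptides: str = "#Peptides"
    n_unique: str = "#Unique"
    intensity_pattern: str = r"^Intensity\s+(?P<channel>\S+)$"
    channel_columns: Mapping[str, str] | None = None
    delimiter: str | None = None  # None -> autodetect comma/tab


PEAKS_X = QuantDialect()


@dataclass
class PlexTable:
    """One TMT experiment: protein rows × channel reporter intensities.

    ``data`` is indexed by accession and carries the metadata columns
    ``gene``, ``description``, ``n_peptides``, ``n_unique_peptides`` plus one
    float column per channel label (missing intensities as NaN).
    """

    plex_id: str
    data: pd.DataFrame
    channel_labels: tuple[str, ...]

    @property
    def accessions(self) -> pd.Index:
        return self.data.index

    @property
    def intensities(self) -> pd.DataFrame:
        """Protein × channel reporter intensity matrix (view)."""
        return self.data.loc[:, list(self.channel_labels)]

    def with_intensities(self, values: pd.DataFrame) -> "PlexTable":
        """Return a copy whose channel columns are replaced by ``values``."""
        data = self.data.copy()
        data.loc[:, list(self.channel_labels)] = values.loc[:, list(self.channel_labels)]
        return PlexTable(self.plex_id, data, self.channel_labels)

    def copy(self) -> "PlexTable":
        return PlexTable(self.plex_id, self.data.copy(), self.channel_labels)

    def validate(self) -> "PlexTable":
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError(
                f"plex {self.plex_id!r}: duplicate channel labels {self.channel_labels}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"plex {self.plex_id!r}: duplicate accessions: {', '.join(map(str, dups))}"
            )
        inten = self.intensities.to_numpy(float)
        if np.nanmin(inten, initial=0.0) < 0:
            raise ValidationError(f"plex {self.plex_id!r}: negative reporter intensities")
        bad = self.data["n_unique_peptides"] > self.data["n_peptides"]
        if bool(bad.any()):
            raise ValidationError(
                f"plex {self.plex_id!r}: n_unique_peptides exceeds n_peptides for "
                f"{', '.join(self.data.index[bad])}"
            )
        return self


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_quant_table(
    path: str | Path,
    plex_id: str | None = None,
    dialect: QuantDialect = PEAKS_X,
) -> PlexTable:
    """Read one per-plex protein quantification table.

    Empty and zero intensity cells become missing markers (NaN).  Raises
    :class:`FormatError` when a mandatory column is absent and
    :class:`ValidationError` on duplicate accessions.
    """
    path = Path(path)
    sep = dialect.delimiter or _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep)

    for col, meaning in (
        (dialect.accession, "accession"),
        (dialect.n_peptides, "peptide count"),
        (dialect.n_unique, "unique peptide count"),
    ):
        if col not in raw.columns:
            raise FormatError(
                f"{path.name}: missing mandatory column {col!r} ({meaning})"
            )

    if dialect.channel_columns is not None:
        channel_map = dict(dialect.channel_columns)
        absent = [c for c in channel_map.values() if c not in raw.columns]
        if absent:
            raise FormatError(
                f"{path.name}: missing reporter-intensity columns {absent}"
            )
    else:
        pattern = re.compile(dialect.intensity_pattern)
        channel_map = {}
        for col in raw.columns:
            match = pattern.match(str(col))
            if match:
                channel_map[match.group("channel")] = col
    if not channel_map:
        raise FormatError(f"{path.name}: no reporter-intensity columns found")

    accessions = raw[dialect.accession].astype(str)
    if accessions.duplicated().any():
        dups = accessions[accessions.duplicated()].unique().tolist()
        raise ValidationError(
            f"{path.name}: duplicate accessions: {', '.join(dups)}"
        )

    data = pd.DataFrame(index=pd.Index(accessions, name="accession"))
    data["gene"] = ""
    if dialect.description in raw.columns:
        data["description"] = raw[dialect.description].fillna("").astype(str).to_numpy()
    else:
        data["description"] = ""
    data["n_peptides"] = raw[dialect.n_peptides].to_numpy(dtype=int)
    data["n_unique_peptides"] = raw[dialect.n_unique].to_numpy(dtype=int)
    for channel, col in channel_map.items():
        values = pd.to_numeric(raw[col], errors="coerce").to_numpy(dtype=float)
        values[values <= 0] = np.nan  # blank/zero -> censored
        data[channel] = values

    table = PlexTable(plex_id or path.stem, data, tuple(channel_map))
    return table.validate()


def write_quant_table(
    table: PlexTable,
    path: str | Path,
    dialect: QuantDialect = PEAKS_X,
) -> None:
    """Write a :class:`PlexTable` back to the quantification dialect.

    Missing intensities are written as blank cells, so
    ``read_quant_table(write_quant_table(t))`` round-trips cell-identically
    for conforming files.
    """
    path = Path(path)
    out = pd.DataFrame()
    out[dialect.accession] = table.data.index
    out[dialect.description] = table.data["description"].to_numpy()
    out[dialect.n_peptides] = table.data["n_peptides"].to_numpy()
    out[dialect.n_unique] = table.data["n_unique_peptides"].to_numpy()
    if dialect.channel_columns is not None:
        names = dict(dialect.channel_columns)
    else:
        names = {ch: f"Intensity {ch}" for ch in table.channel_labels}
    for channel in table.channel_labels:
        out[names[channel]] = table.data[channel].to_numpy()
    sep = dialect.delimiter or ","
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# channel design
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = (
    "plex_id",
    "channel",
    "strain",
    "condition",
    "phase",
    "bio_replicate",
    "tech_replicate",
    "is_bridge",
)

SAMPLE_LEVELS = ("strain", "condition", "phase", "bio_replicate", "tech_replicate")


@dataclass
class ChannelDesign:
    """Map from (plex, channel) to biological sample coordinates.

    Bridge channels are flagged with ``is_bridge``; their strain/condition/
    phase fields describe the composition of the reference pool.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        frame = self.frame.copy()
        frame["channel"] = frame["channel"].astype(str)
        frame["plex_id"] = frame["plex_id"].astype(str)
        frame["is_bridge"] = frame["is_bridge"].astype(bool)
        frame["bio_replicate"] = frame["bio_replicate"].astype(int)
        frame["tech_replicate"] = frame["tech_replicate"].astype(int)
        key = frame[["plex_id", "channel"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (plex, channel) entries: {dups}")
        self.frame = frame.reset_index(drop=True)

    def for_plex(self, plex_id: str) -> pd.DataFrame:
        return self.frame[self.frame["plex_id"] == str(plex_id)]

    def bridge_channels(self, plex_id: str) -> list[str]:
        sub = self.for_plex(plex_id)
        return sub.loc[sub["is_bridge"], "channel"].tolist()

    def sample_entries(self, plex_id: str) -> pd.DataFrame:
        sub = self.for_plex(plex_id)
        return sub.loc[~sub["is_bridge"]]

    def check_coverage(self, table: PlexTable) -> None:
        """Raise unless every channel of the plex has a design entry."""
        sub = self.for_plex(table.plex_id)
        covered = set(sub["channel"])
        uncovered = [c for c in table.channel_labels if c not in covered]
        if uncovered:
            raise ConfigurationError(
                f"design does not cover channels {uncovered} of plex {table.plex_id!r}"
            )

    def validate_against(self, table: PlexTable) -> None:
        """Raise :class:`ConfigurationError` unless this design covers the plex
        and provides at least one bridge channel for it."""
        self.check_coverage(table)
        if not self.bridge_channels(table.plex_id):
            raise ConfigurationError(
                f"design defines no bridge channel for plex {table.plex_id!r}"
            )


def read_design(path: str | Path) -> ChannelDesign:
    """Read a TSV channel design table."""
    frame = pd.read_csv(path, sep="\t")
    return ChannelDesign(frame)


def write_design(design: ChannelDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# identification-level filters
# ---------------------------------------------------------------------------

def filter_identifications(
    table: PlexTable,
    min_unique: int = 2,
    min_replicates: int = 1,
    design: ChannelDesign | None = None,
) -> PlexTable:
    """Apply identification-level filters and return a new table.

    Retains rows with ``n_unique_peptides >= min_unique`` and, when
    ``min_replicates > 1``, with non-missing intensity in at least that many
    distinct biological replicates of at least one strain×condition×phase
    group among the plex's own (non-bridge) channels.  The input is unchanged.
    """
    if min_unique < 1 or min_replicates < 1:
        raise ValidationError("min_unique and min_replicates must be >= 1")
    keep = table.data["n_unique_peptides"] >= min_unique
    if min_replicates > 1:
        if design is None:
            raise ConfigurationError(
                "min_replicates > 1 requires a channel design"
            )
        design.check_coverage(table)
        entries = design.sample_entries(table.plex_id)
        best = pd.Series(0, index=table.data.index)
        for _, group in entries.groupby(["strain", "condition", "phase"]):
            present_reps = []
            for rep, rep_rows in group.groupby("bio_replicate"):
                channels = [c for c in rep_rows["channel"] if c in table.channel_labels]
                present_reps.append(table.intensities[channels].notna().any(axis=1))
            if present_reps:
                count = pd.concat(present_reps, axis=1).sum(axis=1)
                best = np.maximum(best, count)
        keep &= best >= min_replicates
    filtered = PlexTable(table.plex_id, table.data.loc[keep].copy(), table.channel_labels)
    return filtered


# ---------------------------------------------------------------------------
# accession → gene mapping and protein grouping
# ---------------------------------------------------------------------------

@dataclass
class AccessionGeneMap:
    """Accession → gene symbol mapping plus an optional protein-group map."""

    genes: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def display_name(self, accession: str) -> str:
        """Gene symbol for ``accession``; the accession itself when unmapped."""
        return self.genes.get(accession, accession)


def read_gene_map(
    path: str | Path,
    group_path: str | Path | None = None,
) -> AccessionGeneMap:
    """Read a two-column (accession, gene) TSV, optionally with a group map.

    Duplicate accessions raise :class:`ValidationError` listing the offenders
    (the mapping must be a function).
    """
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["accession", "gene"], dtype=str)
    if frame["accession"].duplicated().any():
        dups = frame["accession"][frame["accession"].duplicated()].unique().tolist()
        raise ValidationError(f"duplicate accessions in gene map: {', '.join(dups)}")
    genes = dict(zip(frame["accession"], frame["gene"]))
    groups: dict[str, str] = {}
    if group_path is not None:
        gframe = pd.read_csv(group_path, sep="\t", header=None, comment="#",
                             names=["accession", "group"], dtype=str)
        if gframe["accession"].duplicated().any():
            dups = gframe["accession"][gframe["accession"].duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate accessions in group map: {', '.join(dups)}"
            )
        groups = dict(zip(gframe["accession"], gframe["group"]))
    return AccessionGeneMap(genes=genes, groups=groups)


def annotate_genes(table: PlexTable, mapping: AccessionGeneMap) -> PlexTable:
    """Fill the ``gene`` column; unmapped accessions keep the accession."""
    out = table.copy()
    out.data["gene"] = [mapping.display_name(a) for a in out.data.index]
    return out


def group_proteins(table: PlexTable, mapping: AccessionGeneMap) -> PlexTable:
    """Merge rows sharing a protein-group id (e.g. near-identical paralogs).

    Within a group, per-channel intensities are summed over present values
    (a group with every member missing stays missing), peptide counts are
    summed, and the accession becomes the group id.  A ``group_partial``
    column flags merged cells built from an incomplete member set.  Rows
    without a group id pass through untouched; an empty map is the identity.
    """
    if not mapping.groups:
        return table.copy()
    data = table.data.copy()
    group_ids = pd.Series(
        [mapping.groups.get(acc) for acc in data.index], index=data.index, dtype=object
    )
    grouped_rows = []
    channels = list(table.channel_labels)
    for gid, members in data[group_ids.notna()].groupby(group_ids.dropna()):
        genes = {g for g in members["gene"] if g}
        if len(genes) > 1:
            warnings.warn(
                f"protein group {gid!r} spans conflicting gene symbols {sorted(genes)}; "
                "using the group id",
                stacklevel=2,
            )
        inten = members[channels]
        present = inten.notna()
        summed = inten.sum(axis=0, min_count=1)
        partial = bool(((present.sum(axis=0) > 0) & (present.sum(axis=0) < len(members))).any())
        row = {
            "gene": gid,
            "description": "; ".join(dict.fromkeys(members["description"])),
            "n_peptides": int(members["n_peptides"].sum()),
            "n_unique_peptides": int(members["n_unique_peptides"].sum()),
            "group_partial": partial,
        }
        row.update(summed.to_dict())
        grouped_rows.append(pd.Series(row, name=gid))
    passthrough = data[group_ids.isna()].copy()
    passthrough["group_partial"] = False
    merged = pd.concat([passthrough, pd.DataFrame(grouped_rows)], axis=0)
    merged.index.name = "accession"
    return PlexTable(table.plex_id, merged, table.channel_labels).validate()


# ---------------------------------------------------------------------------
# labeling QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsmRecord:
    """One PSM with its modification sites (position 0 = peptide N-terminus)."""

    psm_id: str
    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()


@dataclass
class PsmModificationTable:
    rows: list[PsmRecord]

    def __post_init__(self) -> None:
        for row in self.rows:
            for pos, name in row.modifications:
                if not 0 <= pos <= len(row.sequence):
                    raise ValidationError(
                        f"PSM {row.psm_id!r}: modification {name!r} at position {pos} "
                        f"outside peptide of length {len(row.sequence)}"
                    )


@dataclass(frozen=True)
class LabelingStats:
    """TMT labeling QC: site-level efficiency and PSM-level overlabeling (%)"""

    efficiency_percent: float
    overlabeling_percent: float
    n_sites: int
    n_labeled_sites: int
    n_psms: int
    n_overlabeled_psms: int


def read_psm_table(path: str | Path) -> PsmModificationTable:
    """Read a PSM modification TSV: psm_id, sequence, ``pos:name;pos:name``."""
    rows = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: expected >=2 tab-separated fields")
            psm_id, sequence = parts[0], parts[1]
            mods: list[tuple[int, str]] = []
            if len(parts) > 2 and parts[2]:
                for token in parts[2].split(";"):
                    pos_str, _, name = token.partition(":")
                    try:
                        mods.append((int(pos_str), name))
                    except ValueError as exc:
                        raise FormatError(f"line {lineno}: bad modification {token!r}") from exc
            rows.append(PsmRecord(psm_id, sequence, tuple(mods)))
    return PsmModificationTable(rows)


def labeling_qc(psms: PsmModificationTable, label_name: str = "TMT10plex") -> LabelingStats:
    """Compute TMT labeling efficiency and overlabeling.

    efficiency = 100 × (labeled K residues + labeled peptide N-termini)
    / (total K residues + total peptide N-termini); overlabeling = 100 × PSMs
    carrying the label on any residue other than K or the N-terminus / PSMs.
    """
    if not psms.rows:
        raise ValidationError("empty PSM table")
    n_sites = 0
    n_labeled = 0
    n_over = 0
    for row in psms.rows:
        n_sites += 1 + row.sequence.count("K")  # N-terminus + lysines
        labeled_positions = {pos for pos, name in row.modifications if name == label_name}
        for pos in labeled_positions:
            if pos == 0 or row.sequence[pos - 1] == "K":
                n_labeled += 1
        if any(pos != 0 and row.sequence[pos - 1] != "K" for pos in labeled_positions):
            n_over += 1
    if n_sites == 0:
        raise UndefinedStatisticError("no available labeling sites")
    return LabelingStats(
        efficiency_percent=100.0 * n_labeled / n_sites,
        overlabeling_percent=100.0 * n_over / len(psms.rows),
        n_sites=n_sites,
        n_labeled_sites=n_labeled,
        n_psms=len(psms.rows),
        n_overlabeled_psms=n_over,
    )


# ---------------------------------------------------------------------------
# proteome FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str
    mw_monoisotopic: float
    mw_average: float


@dataclass
class ProteomeDB:
    """Accession → protein record with sequence and molecular weights."""

    records: dict[str, ProteinRecord]

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.records[accession]

    def accessions(self) -> list[str]:
        return list(self.records)


def sequence_masses(sequence: str) -> tuple[float, float]:
    """(monoisotopic, average) molecular weight of an intact protein/peptide.

    Returns ``(nan, nan)`` when the sequence contains residues outside the
    20 canonical amino acids.
    """
    if set(sequence) <= CANONICAL_RESIDUES:
        mono = _pmass.calculate_mass(sequence=sequence, average=False)
        avg = _pmass.calculate_mass(sequence=sequence, average=True)
        return float(mono), float(avg)
    return float("nan"), float("nan")


def _accession_from_header(header: str) -> str:
    token = header.split()[0]
    try:
        parsed = _pfasta.parse(header)
        if "id" in parsed:
            return parsed["id"]
    except Exception:
        pass
    if token.count("|") == 2:  # UniProt db|ACC|NAME
        return token.split("|")[1]
    return token


def read_fasta(
    path: str | Path,
    extra_residues: Iterable[str] = DEFAULT_EXTRA_RESIDUES,
) -> ProteomeDB:
    """Read a proteome FASTA (UniProt header dialect) into a :class:`ProteomeDB`.

    Sequences must be non-empty and restricted to the canonical residues plus
    ``extra_residues``; sequences containing extras are kept but get NaN
    molecular weights (with a warning), since non-canonical residues have no
    defined monoisotopic mass here.
    """
    allowed = CANONICAL_RESIDUES | set(extra_residues)
    # structural pre-scan: catch header-only records with the line number
    # (lenient parsers silently merge them into the next header)
    with open(path, "r", encoding="utf-8") as handle:
        last_header_line = None
        has_sequence = True
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if stripped.startswith(">"):
                if not has_sequence:
                    raise FormatError(
                        f"line {last_header_line}: record has empty sequence"
                    )
                last_header_line = lineno
                has_sequence = False
            elif stripped:
                has_sequence = True
        if last_header_line is None:
            raise FormatError("no FASTA records found")
        if not has_sequence:
            raise FormatError(f"line {last_header_line}: record has empty sequence")
    records: dict[str, ProteinRecord] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for idx, (header, seq) in enumerate(_pfasta.read(handle), start=1):
            seq = seq.strip().upper().rstrip("*")
            if not seq:
                raise FormatError(f"record {idx}: empty sequence")
            bad = set(seq) - allowed
            if bad:
                raise FormatError(
                    f"record {idx}: residues {sorted(bad)} outside allowed alphabet"
                )
            accession = _accession_from_header(header)
            if accession in records:
                raise ValidationError(f"duplicate accession {accession!r} in FASTA")
            mono, avg = sequence_masses(seq)
            if np.isnan(mono):
                warnings.warn(
                    f"{accession}: non-canonical residues; excluded from mass computation",
                    stacklevel=2,
                )
            records[accession] = ProteinRecord(accession, header, seq, mono, avg)
    return ProteomeDB(records)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, GeneSet] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"line {lineno}: GMT line needs name, description and >=1 gene"
                )
            name, description = parts[0], parts[1]
            genes = tuple(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise FormatError(f"line {lineno}: gene set {name!r} has no members")
            sets[name] = GeneSet(name, description, genes)
    return GeneSetCollection(sets)
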