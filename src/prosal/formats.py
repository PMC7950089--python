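"""Readers, writers and validators for the tabular and sequence formats the
pipeline touches.

All tables are plain TSV (UTF-8, no thousands separators).  Missing
measurements are encoded as ``.`` or an empty cell and parsed as missing —
never as zero; a literal ``0`` is a present measurement.  Readers reject
malformed input instead of coercing it, and every writer produces files its
paired reader accepts round-trip.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("prosal")

#: The 20 canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Marker used for window positions that fall outside the parent protein.
TERMINUS_MARKER = "-"

#: Strings parsed as a missing measurement in any quantitative TSV.
MISSING_MARKERS = ("", ".", "NA", "NaN", "nan")

GROUP_NEGATIVE = "pN0"
GROUP_POSITIVE = "pN+"
GROUPS = (GROUP_NEGATIVE, GROUP_POSITIVE)

#: Schechter–Berger positions supported by the rule schema, N→C order.
RULE_POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

#: Positions reconstructed by default from peptide/protein context.
WINDOW_POSITIONS = ("P3", "P2", "P1", "P1'", "P2'", "P3'")


# ---------------------------------------------------------------------------
# Protein records / FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein database entry: UniProt-style accession plus sequence."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"{self.accession}: illegal residue {aa!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_unique_accessions(records: list[ProteinRecord]) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.accession] = seen.get(rec.accession, 0) + 1
    dups = sorted(a for a, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate accessions: {', '.join(dups)}")


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated :class:`ProteinRecord` s."""
    records = [
        ProteinRecord(
            accession=rec.id,
            sequence=str(rec.seq).upper(),
            description=rec.description[len(rec.id):].strip(),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_accessions(records)
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    _check_unique_accessions(list(records))
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def proteome_index(records: list[ProteinRecord]) -> dict[str, ProteinRecord]:
    _check_unique_accessions(list(records))
    return {r.accession: r for r in records}


# ---------------------------------------------------------------------------
# Quantitative tables
# ---------------------------------------------------------------------------

def _parse_intensity_frame(raw: pd.DataFrame, samples: list[str], where: str) -> pd.DataFrame:
    """Parse sample columns to float with missing markers → NaN; reject negatives."""
    out = {}
    for s in samples:
        col = raw[s]
        if col.dtype == object:
            col = col.astype(str).str.strip()
            col = col.mask(col.isin(MISSING_MARKERS))
        col = pd.to_numeric(col, errors="raise").astype(float)
        if (col.dropna() < 0).any():
            bad = col[col < 0].index[0]
            raise ValueError(f"{where}: negative intensity in sample {s!r}, row {bad}")
        out[s] = col
    return pd.DataFrame(out, index=raw.index)


@dataclass
class PeptideQuantTable:
    """Peptide-level label-free quant table.

    ``data`` is indexed by ``peptide_id`` and carries the annotation columns
    ``sequence``, ``proteins`` (semicolon-joined accessions, first entry the
    leading protein) and ``quality`` followed by one float column per sample
    (NaN = missing).  ``group_map`` assigns every sample column to exactly one
    group.
    """

    data: pd.DataFrame
    group_map: dict[str, str]

    ANNOT = ("sequence", "proteins", "quality")

    def __post_init__(self):
        missing = [c for c in self.ANNOT if c not in self.data.columns]
        if missing:
            raise ValueError(f"quant table missing columns: {missing}")
        if not self.data.index.is_unique:
            raise ValueError("peptide_id index must be unique")
        for s in self.samples:
            if s not in self.group_map:
                raise ValueError(f"sample column {s!r} not assigned to a group")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.ANNOT]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_map[s] == group]

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_map.values()))

    @property
    def intensities(self) -> pd.DataFrame:
        return self.data[self.samples].astype(float)

    def with_data(self, data: pd.DataFrame) -> "PeptideQuantTable":
        return PeptideQuantTable(data=data, group_map=dict(self.group_map))

    def leading_protein(self, peptide_id: str) -> str:
        return str(self.data.at[peptide_id, "proteins"]).split(";")[0]

    def __len__(self) -> int:
        return len(self.data)


def read_quant_table(path, group_map: dict[str, str]) -> PeptideQuantTable:
    """Read a peptide quant TSV (peptide_id, sequence, proteins, quality, samples...)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("peptide_id", "sequence", "proteins", "quality"):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    raw = raw.set_index("peptide_id")
    absent = [s for s in group_map if s not in raw.columns]
    if absent:
        raise ValueError(f"{path}: samples in group map absent from header: {absent}")
    samples = [c for c in raw.columns if c in group_map]
    inten = _parse_intensity_frame(raw[samples], samples, str(path))
    data = pd.concat(
        [raw[["sequence", "proteins"]],
         pd.to_numeric(raw["quality"], errors="raise").rename("quality"),
         inten],
        axis=1,
    )
    logger.info("read %d peptides x %d samples from %s", len(data), len(samples), path)
    return PeptideQuantTable(data=data, group_map=dict(group_map))


def write_quant_table(table: PeptideQuantTable, path) -> None:
    out = table.data.copy()
    out.index.name = "peptide_id"
    out.to_csv(path, sep="\t", na_rep=".", float_format="%.6g")


@dataclass
class ProteinQuantTable:
    """Protein-group LFQ table (MaxQuant-proteinGroups-like minimal dialect).

    ``data`` is indexed by accession with boolean ``is_reverse`` and
    ``only_by_site`` columns, a ``class_tag`` in {protease,
    protease_inhibitor, other}, and per-sample LFQ intensity columns.
    """

    data: pd.DataFrame
    group_map: dict[str, str]

    ANNOT = ("is_reverse", "only_by_site", "class_tag")
    CLASS_TAGS = ("protease", "protease_inhibitor", "other")

    def __post_init__(self):
        missing = [c for c in self.ANNOT if c not in self.data.columns]
        if missing:
            raise ValueError(f"protein table missing columns: {missing}")
        if not self.data.index.is_unique:
            raise ValueError("accession index must be unique")
        bad = set(self.data["class_tag"]) - set(self.CLASS_TAGS)
        if bad:
            raise ValueError(f"unknown class tags: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.ANNOT]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_map[s] == group]

    def with_data(self, data: pd.DataFrame) -> "ProteinQuantTable":
        return ProteinQuantTable(data=data, group_map=dict(self.group_map))

    def __len__(self) -> int:
        return len(self.data)


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False, "+": True, "": False}


def read_protein_table(path, group_map: dict[str, str]) -> ProteinQuantTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "is_reverse", "only_by_site", "class_tag"):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    raw = raw.set_index("accession")
    samples = [c for c in raw.columns if c in group_map]
    absent = [s for s in group_map if s not in raw.columns]
    if absent:
        raise ValueError(f"{path}: samples absent from header: {absent}")
    flags = {}
    for col in ("is_reverse", "only_by_site"):
        low = raw[col].str.strip().str.lower()
        unknown = set(low) - set(_BOOL)
        if unknown:
            raise ValueError(f"{path}: non-boolean {col} values {sorted(unknown)}")
        flags[col] = low.map(_BOOL)
    inten = _parse_intensity_frame(raw[samples], samples, str(path))
    data = pd.concat(
        [pd.DataFrame(flags, index=raw.index), raw[["class_tag"]], inten], axis=1
    )
    return ProteinQuantTable(data=data, group_map=dict(group_map))


def write_protein_table(table: ProteinQuantTable, path) -> None:
    out = table.data.copy()
    out.index.name = "accession"
    out.to_csv(path, sep="\t", na_rep=".", float_format="%.6g")


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """Per-sample clinical covariates.

    ``data`` is indexed by sample_id with a ``group`` column (pN0/pN+) and
    numerically coded binary/ordinal features (NaN = missing).
    """

    data: pd.DataFrame

    def __post_init__(self):
        if "group" not in self.data.columns:
            raise ValueError("clinical table requires a 'group' column")
        if not self.data.index.is_unique:
            raise ValueError("sample_id index must be unique")
        bad = set(self.data["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")

    @property
    def features(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]

    @property
    def group_map(self) -> dict[str, str]:
        return dict(self.data["group"])

    def __len__(self) -> int:
        return len(self.data)


def read_clinical_table(path) -> ClinicalTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns or "group" not in raw.columns:
        raise ValueError(f"{path}: clinical table requires sample_id and group columns")
    raw = raw.set_index("sample_id")
    feats = {}
    for col in raw.columns:
        if col == "group":
            continue
        vals = raw[col].str.strip().replace(list(MISSING_MARKERS), np.nan)
        feats[col] = pd.to_numeric(vals, errors="raise")
    data = pd.concat([raw[["group"]], pd.DataFrame(feats, index=raw.index)], axis=1)
    return ClinicalTable(data=data)


def write_clinical_table(table: ClinicalTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=".", float_format="%g")


# ---------------------------------------------------------------------------
# Protease cleavage-site rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteaseRule:
    """One literature-derived protease ↔ cleavage-site association.

    ``positions`` maps a subset of P4..P4' to the admissible residue set at
    that position; unconstrained positions are simply absent.  Octamer-style
    rules (exact P4..P4' string with X wildcards and an optional ``|`` at the
    scissile bond) are normalized to this representation on load.
    """

    protease_id: str
    positions: dict[str, frozenset]
    evidence: str = ""

    def __post_init__(self):
        if not self.positions:
            raise ValueError(f"{self.protease_id}: rule constrains no position")
        for pos, residues in self.positions.items():
            if pos not in RULE_POSITIONS:
                raise ValueError(f"{self.protease_id}: unknown position {pos!r}")
            if not residues:
                raise ValueError(f"{self.protease_id}: empty residue set at {pos}")
            bad = set(residues) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"{self.protease_id}: illegal residues {sorted(bad)} at {pos}")

    def describe(self) -> str:
        parts = [f"{p}={{{''.join(sorted(self.positions[p]))}}}"
                 for p in RULE_POSITIONS if p in self.positions]
        return f"{self.protease_id}: " + ", ".join(parts)

    # offset of each Schechter–Berger position from the scissile bond, where
    # ``cut`` counts the residues N-terminal to the bond (1-based P1 index)
    _OFFSETS = {"P4": -4, "P3": -3, "P2": -2, "P1": -1,
                "P1'": 0, "P2'": 1, "P3'": 2, "P4'": 3}

    def matches_cut(self, sequence: str, cut: int) -> bool:
        """True iff the bond after ``cut`` residues satisfies every constraint.

        Constrained positions falling outside the protein never match.
        """
        for pos, allowed in self.positions.items():
            idx = cut + self._OFFSETS[pos]
            if idx < 0 or idx >= len(sequence):
                return False
            if sequence[idx] not in allowed:
                return False
        return True

    def cut_sites(self, sequence: str) -> list[int]:
        """All internal bond positions of ``sequence`` satisfying the rule."""
        return [c for c in range(1, len(sequence)) if self.matches_cut(sequence, c)]


def parse_octamer(octamer: str) -> dict[str, frozenset]:
    """Normalize an exact-site octamer like ``XXXQ|GXXX`` to positional sets."""
    site = octamer.strip().upper()
    if "|" in site:
        nterm, cterm = site.split("|")
        if len(nterm) > 4 or len(cterm) > 4:
            raise ValueError(f"octamer {octamer!r}: more than 4 residues on one side")
        nterm = nterm.rjust(4, "X")
        cterm = cterm.ljust(4, "X")
        site = nterm + cterm
    if len(site) != 8:
        raise ValueError(f"octamer {octamer!r}: expected 8 positions (P4..P4')")
    positions = {}
    for pos, aa in zip(RULE_POSITIONS, site):
        if aa == "X":
            continue
        if aa not in AMINO_ACIDS:
            raise ValueError(f"octamer {octamer!r}: illegal residue {aa!r}")
        positions[pos] = frozenset(aa)
    return positions


def _parse_positional_sets(spec: str) -> dict[str, frozenset]:
    """Parse ``P1=FWYL; P1'=G`` style positional residue sets."""
    positions = {}
    for chunk in spec.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed positional set {chunk!r}")
        pos, residues = chunk.split("=", 1)
        residues = residues.strip().strip("{}")
        positions[pos.strip()] = frozenset(residues)
    return positions


def read_rule_table(path) -> list[ProteaseRule]:
    """Read and validate a protease rule TSV.

    Columns: protease_id, rule_kind ∈ {site_octamer, positional_sets}, rule,
    evidence.  Every rule is normalized to positional sets.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protease_id", "rule_kind", "rule"):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    rules = []
    for _, row in raw.iterrows():
        kind = row["rule_kind"].strip()
        if kind == "site_octamer":
            positions = parse_octamer(row["rule"])
        elif kind == "positional_sets":
            positions = _parse_positional_sets(row["rule"])
        else:
            raise ValueError(f"{path}: unknown rule_kind {kind!r}")
        evidence = row["evidence"].strip() if "evidence" in raw.columns else ""
        rules.append(ProteaseRule(
            protease_id=row["protease_id"].strip(),
            positions=positions,
            evidence=evidence,
        ))
    validate_rule_table(rules)
    return rules


def validate_rule_table(rules: list[ProteaseRule]) -> list[ProteaseRule]:
    if not rules:
        raise ValueError("rule table is empty")
    # dataclass validation already enforces non-empty constraint sets
    return rules


def write_rule_table(rules: list[ProteaseRule], path) -> None:
    rows = []
    for r in rules:
        spec = "; ".join(
            f"{p}={''.join(sorted(r.positions[p]))}"
            for p in RULE_POSITIONS if p in r.positions
        )
        rows.append({"protease_id": r.protease_id, "rule_kind": "positional_sets",
                     "rule": spec, "evidence": r.evidence})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_rule_table() -> list[ProteaseRule]:
    """The packaged illustrative rule table (literature-style examples).

    These rules are illustrative specificities for proteases discussed in the
    salivary-proteolysis context; they are not a reconstruction of any
    curated cleavage-site database.  Real analyses should supply their own
    literature table.
    """
    ref = importlib.resources.files("prosal") / "data" / "protease_rules.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_rule_table(path)


# ---------------------------------------------------------------------------
# SRM transition / area tables
# ---------------------------------------------------------------------------

TRANSITION_COLUMNS = ("protein", "peptide", "precursor_charge", "fragment",
                      "channel", "mz")

SRM_MEASUREMENT_COLUMNS = ("sample_id", "group", "replicate", "peptide",
                           "fragment", "light_area", "heavy_area")


def read_transition_table(path) -> pd.DataFrame:
    """Read an SRM transition list (one row per peptide/fragment/channel)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing transition columns {missing}")
    if (df["precursor_charge"] < 1).any():
        raise ValueError(f"{path}: precursor charge must be ≥ 1")
    bad = set(df["channel"]) - {"light", "heavy"}
    if bad:
        raise ValueError(f"{path}: unknown channels {sorted(bad)}")
    return df


def read_srm_measurements(path) -> pd.DataFrame:
    """Read per-replicate SRM peak areas (light and heavy channels)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SRM_MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SRM columns {missing}")
    for col in ("light_area", "heavy_area"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"{path}: negative {col}")
    return df
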