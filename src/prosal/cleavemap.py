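"""Peptide-to-protein mapping, cleavage-window reconstruction and
position-specific residue enrichment.

Endogenous peptides are exact substrings of their parent proteins; the six
residues flanking each peptide boundary (P3–P1 before the scissile bond,
P1'–P3' after it, Schechter–Berger numbering) reconstruct the putative
cleavage site.  Residue frequencies per position are compared against the
background composition of the proteome with a two-sided normal-approximation
z-test (an exact binomial alternative is available), the statistic families
used by sequence-logo enrichment tools.

Coordinates are 1-based inclusive throughout; the cut position is the
1-based index of P1.  Window cells that fall outside the protein carry the
terminus marker and are excluded from enrichment counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import (
    AMINO_ACIDS,
    TERMINUS_MARKER,
    WINDOW_POSITIONS,
    PeptideQuantTable,
    ProteinRecord,
    proteome_index,
)

logger = logging.getLogger("prosal")


# ---------------------------------------------------------------------------
# Locating peptides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideLocation:
    peptide_id: str
    accession: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    ambiguous: bool = False


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def locate_peptides(
    table: PeptideQuantTable,
    proteome: list[ProteinRecord],
    restrict_to_assigned: bool = True,
) -> tuple[list[PeptideLocation], list[str]]:
    """Exact substring matching of peptides onto full-length proteins.

    With ``restrict_to_assigned`` only the accessions listed in the quant
    table's ``proteins`` column are searched; otherwise the whole proteome.
    All matches are returned, flagged ambiguous when a peptide has more than
    one distinct (protein, start).  Peptides with no match are returned in
    the second element, never silently dropped.
    """
    index = proteome_index(proteome)
    locations: list[PeptideLocation] = []
    unmatched: list[str] = []
    for pid, row in table.data.iterrows():
        seq = str(row["sequence"])
        if restrict_to_assigned:
            accs = [a for a in str(row["proteins"]).split(";") if a]
            targets = [(a, index[a]) for a in accs if a in index]
        else:
            targets = list(index.items())
        hits = []
        for acc, rec in targets:
            for off in _all_occurrences(rec.sequence, seq):
                hits.append((acc, off + 1, off + len(seq)))
        if not hits:
            unmatched.append(pid)
            continue
        ambiguous = len(hits) > 1
        for acc, start, end in hits:
            locations.append(PeptideLocation(pid, acc, start, end, ambiguous))
    if unmatched:
        logger.warning("%d peptides had no exact match in the proteome",
                       len(unmatched))
    return locations, unmatched


# ---------------------------------------------------------------------------
# Cleavage windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageWindow:
    """P3..P3' context of one reconstructed cleavage site.

    ``side`` is "N" for the bond releasing the peptide's N terminus and "C"
    for its C terminus; ``cut`` is the 1-based index of P1 in the protein.
    ``residues`` maps P3..P3' (optionally P4/P4' in wide mode) to a residue
    or the terminus marker.
    """

    peptide_id: str
    accession: str
    side: str
    cut: int
    residues: tuple[tuple[str, str], ...]  # ordered (position, residue)

    def residue_at(self, position: str) -> str:
        return dict(self.residues)[position]

    def site_string(self) -> str:
        d = dict(self.residues)
        nterm = "".join(d.get(p, "") for p in ("P4", "P3", "P2", "P1"))
        cterm = "".join(d.get(p, "") for p in ("P1'", "P2'", "P3'", "P4'"))
        return f"{nterm}|{cterm}"


def _window_at(sequence: str, cut: int, width: int) -> tuple[tuple[str, str], ...]:
    positions = WINDOW_POSITIONS if width == 3 else (
        ("P4",) + WINDOW_POSITIONS + ("P4'",))
    out = []
    offsets = {"P4": -4, "P3": -3, "P2": -2, "P1": -1,
               "P1'": 0, "P2'": 1, "P3'": 2, "P4'": 3}
    for pos in positions:
        idx = cut + offsets[pos]
        if 0 <= idx < len(sequence):
            out.append((pos, sequence[idx]))
        else:
            out.append((pos, TERMINUS_MARKER))
    return tuple(out)


def extract_windows(
    location: PeptideLocation,
    proteome: list[ProteinRecord] | dict[str, ProteinRecord],
    width: int = 3,
) -> list[CleavageWindow]:
    """Reconstruct the N- and C-side cleavage windows of one location.

    The N-side window exists iff the peptide does not start at the protein
    N terminus, the C-side iff it does not end at the C terminus.  Window
    positions beyond the protein ends are padded with the terminus marker,
    never with invented residues.
    """
    if width not in (3, 4):
        raise ValueError("window width must be 3 or 4")
    index = proteome if isinstance(proteome, dict) else proteome_index(proteome)
    rec = index[location.accession]
    seq = rec.sequence
    if not (1 <= location.start <= location.end <= len(seq)):
        raise ValueError(f"{location.peptide_id}: location outside protein")
    windows = []
    if location.start > 1:
        cut = location.start - 1  # bond between start-1 and start
        windows.append(CleavageWindow(
            peptide_id=location.peptide_id, accession=location.accession,
            side="N", cut=cut, residues=_window_at(seq, cut, width)))
    if location.end < len(seq):
        cut = location.end  # bond between end and end+1
        windows.append(CleavageWindow(
            peptide_id=location.peptide_id, accession=location.accession,
            side="C", cut=cut, residues=_window_at(seq, cut, width)))
    return windows


def windows_for_table(
    table: PeptideQuantTable,
    proteome: list[ProteinRecord],
    restrict_to_assigned: bool = True,
    width: int = 3,
) -> tuple[list[CleavageWindow], list[str]]:
    """Locate every peptide and extract all cleavage windows."""
    index = proteome_index(proteome)
    locations, unmatched = locate_peptides(table, proteome, restrict_to_assigned)
    windows = []
    for loc in locations:
        windows.extend(extract_windows(loc, index, width))
    return windows, unmatched


def windows_to_frame(windows: list[CleavageWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        row = {"peptide_id": w.peptide_id, "accession": w.accession,
               "side": w.side, "cut": w.cut}
        row.update(dict(w.residues))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Background composition and enrichment
# ---------------------------------------------------------------------------

def background_composition(proteome: list[ProteinRecord]) -> pd.Series:
    """Residue frequencies over all residues of all proteome sequences."""
    if not proteome:
        raise ValueError("empty proteome")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for rec in proteome:
        for aa in rec.sequence:
            counts[aa] += 1
    total = sum(counts.values())
    return pd.Series({aa: counts[aa] / total for aa in AMINO_ACIDS},
                     name="frequency")


@dataclass
class LogoResult:
    """Position × residue enrichment of cleavage windows vs background.

    ``difference`` holds observed − background frequency in percentage
    points; ``z`` and ``p`` the test statistic and two-sided p-value;
    ``direction`` is "over"/"under" where p ≤ alpha, "ns" otherwise.
    ``n_windows`` counts the non-terminus cells used per position.
    """

    difference: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    direction: pd.DataFrame
    n_windows: pd.Series
    alpha: float

    def top_enriched(self, position: str) -> str | None:
        """Most over-represented residue at a position (max z among 'over')."""
        over = self.direction.loc[position] == "over"
        if not over.any():
            return None
        return self.z.loc[position][over].idxmax()


def _dedupe_windows(windows: list[CleavageWindow]) -> list[CleavageWindow]:
    # one distinct window per peptide: duplicate (peptide, side, residues)
    # combinations from multi-protein matches are collapsed so a peptide is
    # counted once, not once per occurrence
    seen = set()
    out = []
    for w in windows:
        key = (w.peptide_id, w.side, tuple(w.residues))
        if key in seen:
            continue
        seen.add(key)
        out.append(w)
    return out


def logo_enrichment(
    windows: list[CleavageWindow],
    background: pd.Series,
    alpha: float = 0.05,
    exclude_accessions: tuple[str, ...] = (),
    method: str = "z",
) -> LogoResult:
    """Position-specific residue enrichment of cleavage windows.

    Windows from ``exclude_accessions`` are dropped first (the route used to
    remove the dominant salivary proline-rich proteins).  Per position and
    residue the observed frequency f_obs over the N usable windows is
    compared with the background frequency f_bg via
    z = (f_obs − f_bg) / sqrt(f_bg (1 − f_bg) / N) and a two-sided normal
    p-value (``method='binomial'`` substitutes the exact binomial test).
    """
    if method not in ("z", "binomial"):
        raise ValueError(f"unknown enrichment method {method!r}")
    excluded = set(exclude_accessions)
    usable = [w for w in _dedupe_windows(windows) if w.accession not in excluded]
    if not usable:
        raise ValueError("no windows left after exclusion")
    positions = [p for p, _ in usable[0].residues]
    residues = list(AMINO_ACIDS)

    diff = pd.DataFrame(0.0, index=positions, columns=residues)
    zmat = pd.DataFrame(0.0, index=positions, columns=residues)
    pmat = pd.DataFrame(1.0, index=positions, columns=residues)
    direction = pd.DataFrame("ns", index=positions, columns=residues)
    n_windows = pd.Series(0, index=positions, dtype=int)

    for pos in positions:
        observed = [dict(w.residues)[pos] for w in usable]
        observed = [aa for aa in observed if aa != TERMINUS_MARKER]
        n = len(observed)
        n_windows[pos] = n
        if n == 0:
            diff.loc[pos] = np.nan
            zmat.loc[pos] = np.nan
            pmat.loc[pos] = np.nan
            continue
        counts = pd.Series(observed).value_counts()
        for aa in residues:
            k = int(counts.get(aa, 0))
            f_obs = k / n
            f_bg = float(background[aa])
            diff.loc[pos, aa] = (f_obs - f_bg) * 100.0
            if f_bg <= 0.0 or f_bg >= 1.0:
                z = 0.0 if f_obs == f_bg else np.inf * np.sign(f_obs - f_bg)
                p = 1.0 if f_obs == f_bg else 0.0
            elif method == "z":
                z = (f_obs - f_bg) / np.sqrt(f_bg * (1.0 - f_bg) / n)
                p = 2.0 * stats.norm.sf(abs(z))
            else:
                z = (f_obs - f_bg) / np.sqrt(f_bg * (1.0 - f_bg) / n)
                p = stats.binomtest(k, n, f_bg, alternative="two-sided").pvalue
            zmat.loc[pos, aa] = z
            pmat.loc[pos, aa] = min(p, 1.0)
            if p <= alpha and f_obs != f_bg:
                direction.loc[pos, aa] = "over" if f_obs > f_bg else "under"

    logger.info("logo enrichment over %d windows (%d excluded by accession)",
                len(usable), len(_dedupe_windows(windows)) - len(usable))
    return LogoResult(difference=diff, z=zmat, p=pmat, direction=direction,
                      n_windows=n_windows, alpha=alpha)
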