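"""Observed-mode protease prediction from reconstructed cleavage windows.

A cleavage window is attributed to a protease when every constrained
position of that protease's literature rule is satisfied by the window's
residue at the same Schechter–Berger position; terminus markers never
satisfy a constraint.  A peptide is attributed to a protease when either of
its boundary windows matches (N- and C-side matched independently).
Matching granularity is the reconstructed P3–P3' context; P4/P4'
constraints can only be evaluated on windows extracted in wide (4-residue)
mode and otherwise fail closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleavemap import CleavageWindow
from .formats import (
    GROUP_NEGATIVE,
    GROUP_POSITIVE,
    TERMINUS_MARKER,
    PeptideQuantTable,
    ProteaseRule,
)

logger = logging.getLogger("prosal")


@dataclass(frozen=True)
class SiteMatch:
    peptide_id: str
    protease_id: str
    side: str
    accession: str
    cut: int
    evidence: str = ""


@dataclass
class PredictionResult:
    """Protease attributions of a window set.

    ``matches`` lists every (peptide, protease, side) attribution;
    ``substrates`` maps protease → sorted unique substrate peptide ids;
    ``unmatched`` lists peptides with windows but no matching rule.
    """

    matches: list[SiteMatch] = field(default_factory=list)
    substrates: dict[str, list[str]] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)

    def proteases(self) -> list[str]:
        return sorted(self.substrates)

    def matched_peptides(self) -> set[str]:
        return {m.peptide_id for m in self.matches}


def window_matches_rule(window: CleavageWindow, rule: ProteaseRule) -> bool:
    """True iff every constrained position is satisfied by the window.

    Constrained positions absent from the window context (P4/P4' on
    standard-width windows) or carrying a terminus marker do not match.
    """
    residues = dict(window.residues)
    for pos, allowed in rule.positions.items():
        aa = residues.get(pos)
        if aa is None or aa == TERMINUS_MARKER or aa not in allowed:
            return False
    return True


def match_sites(
    windows: list[CleavageWindow],
    rules: list[ProteaseRule],
) -> PredictionResult:
    """Match every window against every rule (observed mode)."""
    result = PredictionResult()
    peptides_seen: set[str] = set()
    attributed: set[str] = set()
    seen_matches: set[tuple] = set()
    for window in windows:
        peptides_seen.add(window.peptide_id)
        for rule in rules:
            if not window_matches_rule(window, rule):
                continue
            key = (window.peptide_id, rule.protease_id, window.side,
                   window.accession, window.cut)
            if key in seen_matches:
                continue
            seen_matches.add(key)
            result.matches.append(SiteMatch(
                peptide_id=window.peptide_id, protease_id=rule.protease_id,
                side=window.side, accession=window.accession, cut=window.cut,
                evidence=rule.evidence))
            attributed.add(window.peptide_id)
    for match in result.matches:
        result.substrates.setdefault(match.protease_id, [])
        if match.peptide_id not in result.substrates[match.protease_id]:
            result.substrates[match.protease_id].append(match.peptide_id)
    for protease in result.substrates:
        result.substrates[protease] = sorted(result.substrates[protease])
    result.unmatched = sorted(peptides_seen - attributed)
    logger.info("observed-mode matching: %d/%d peptides attributed to %d proteases",
                len(attributed), len(peptides_seen), len(result.substrates))
    return result


def matches_to_frame(result: PredictionResult) -> pd.DataFrame:
    return pd.DataFrame([{
        "peptide_id": m.peptide_id, "protease_id": m.protease_id,
        "side": m.side, "accession": m.accession, "cut": m.cut,
        "evidence": m.evidence,
    } for m in result.matches])


def aggregate_substrate_abundance(
    result: PredictionResult,
    quant: PeptideQuantTable,
    mode: str = "sum",
) -> pd.DataFrame:
    """Protease × sample matrix of aggregated substrate intensities.

    Per protease and sample the present intensities of its substrate
    peptides are summed (or averaged); cells where no substrate was measured
    are missing.  Proteases whose substrates are entirely absent from the
    quant table yield all-missing rows and a warning.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    samples = quant.samples
    rows = {}
    for protease in result.proteases():
        ids = [pid for pid in result.substrates[protease]
               if pid in quant.data.index]
        if not ids:
            logger.warning("protease %s: no substrate present in quant table",
                           protease)
            rows[protease] = pd.Series(np.nan, index=samples)
            continue
        block = quant.data.loc[ids, samples].astype(float)
        agg = block.sum(axis=0, min_count=1) if mode == "sum" \
            else block.mean(axis=0)
        rows[protease] = agg
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "protease_id"
    matrix.attrs["aggregation"] = mode
    return matrix


def group_summary(matrix: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """Per-protease group means of the aggregated substrate abundance."""
    neg = [s for s in matrix.columns if group_map[s] == GROUP_NEGATIVE]
    pos = [s for s in matrix.columns if group_map[s] == GROUP_POSITIVE]
    out = pd.DataFrame({
        "mean_pN0": matrix[neg].mean(axis=1),
        "mean_pN+": matrix[pos].mean(axis=1),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_ratio"] = np.log2(out["mean_pN+"] / out["mean_pN0"])
    return out


def rank_proteases(
    result: PredictionResult,
    quant: PeptideQuantTable,
) -> list[str]:
    """Deterministic protease ranking by substrate count, then abundance.

    Primary key: number of substrate peptides (descending); secondary:
    total present substrate intensity (descending); ties broken
    lexicographically by protease id.
    """
    if not result.substrates:
        raise ValueError("empty prediction result")
    matrix = aggregate_substrate_abundance(result, quant, mode="sum")
    totals = matrix.sum(axis=1, skipna=True)
    keys = []
    for protease in result.proteases():
        keys.append((-len(result.substrates[protease]),
                     -float(totals.get(protease, 0.0)), protease))
    return [k[2] for k in sorted(keys)]
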