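"""End-to-end orchestration: synthetic study → filtering → differential →
cleavage/logo → protease prediction → clinical association/ROC → SRM.

Thin glue over the analysis modules, used by the command line and the
integration tests.  All outputs are plain TSV/JSON and are byte-stable for
a fixed seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinstats, cleavemap, proteasepred, quantops, srmtools, syndata
from .formats import (
    GROUP_POSITIVE,
    default_rule_table,
    write_clinical_table,
    write_fasta,
    write_quant_table,
)

logger = logging.getLogger("prosal")


def run_pipeline(seed: int, outdir: str | Path,
                 config: syndata.SyntheticConfig | None = None) -> dict:
    """Run the whole analysis chain on a synthetic study and write outputs.

    Writes proteome FASTA, quant/clinical/truth inputs, then filtered and
    differential tables, cleavage windows, logo matrices, protease matches
    and substrate abundances, ROC records, and SRM quantification results.
    Returns a summary dict (also written to ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or syndata.default_config(seed)

    proteome, peptides, quant, clinical, truth = syndata.simulate_study(config)
    write_fasta(proteome, outdir / "proteome.fasta")
    write_quant_table(quant, outdir / "quant_raw.tsv")
    write_clinical_table(clinical, outdir / "clinical.tsv")
    truth.to_json(outdir / "truth.json")

    # quantitative filtering and differential analysis
    filtered = quantops.filter_quality(quant, config.quality_threshold)
    filtered = quantops.filter_valid_values(filtered, min_per_group=1)
    normalized = quantops.normalize_intensities(filtered, method="median")
    partition = quantops.exclusivity_partition(quant)
    diff = quantops.differential_anova(normalized, alpha=0.05)
    write_quant_table(normalized, outdir / "quant_filtered.tsv")
    diff.to_csv(outdir / "differential.tsv", sep="\t", na_rep=".",
                float_format="%.6g")

    diff_ids = diff.index[diff["significant"]].tolist()
    diff_table = normalized.with_data(normalized.data.loc[diff_ids].copy())

    # cleavage-site reconstruction and enrichment
    windows, unmatched = cleavemap.windows_for_table(diff_table, proteome)
    background = cleavemap.background_composition(proteome)
    cleavemap.windows_to_frame(windows).to_csv(
        outdir / "windows.tsv", sep="\t", index=False)
    logo_summary = {}
    if windows:
        logo = cleavemap.logo_enrichment(windows, background, alpha=0.05)
        logo.difference.to_csv(outdir / "logo_difference.tsv", sep="\t",
                               float_format="%.6g")
        logo.z.to_csv(outdir / "logo_z.tsv", sep="\t", float_format="%.6g")
        logo.p.to_csv(outdir / "logo_p.tsv", sep="\t", float_format="%.6g")
        logo_summary = {
            "n_windows": {p: int(n) for p, n in logo.n_windows.items()},
            "top_P1": logo.top_enriched("P1"),
        }

    # protease prediction
    rules = [rule for rule, _ in config.planted_proteases] or default_rule_table()
    prediction = proteasepred.match_sites(windows, rules)
    proteasepred.matches_to_frame(prediction).to_csv(
        outdir / "protease_matches.tsv", sep="\t", index=False)
    ranking = []
    if prediction.substrates:
        matrix = proteasepred.aggregate_substrate_abundance(
            prediction, normalized, mode="sum")
        matrix.to_csv(outdir / "substrate_abundance.tsv", sep="\t",
                      na_rep=".", float_format="%.6g")
        proteasepred.group_summary(matrix, normalized.group_map).to_csv(
            outdir / "substrate_group_summary.tsv", sep="\t", na_rep=".",
            float_format="%.6g")
        ranking = proteasepred.rank_proteases(prediction, normalized)

    # clinical association and ROC
    assoc = clinstats.correlate_clinical(normalized, clinical)
    assoc.to_csv(outdir / "clinical_association.tsv", sep="\t", na_rep=".",
                 index=False, float_format="%.6g")
    labels = np.array([
        1 if normalized.group_map[s] == GROUP_POSITIVE else 0
        for s in normalized.samples
    ])
    detected = clinstats.detection_rate_filter(normalized, min_rate=0.85)
    roc_records = []
    for pid in detected[:5]:
        rec = clinstats.roc_single(
            normalized.intensities.loc[pid], labels,
            method="logistic", seed=seed, feature_id=pid)
        roc_records.append(rec.to_dict())
    panel_auc = None
    if len(detected) >= 2:
        panel_features = np.log2(
            normalized.intensities.loc[detected[:5]].T + 1.0)
        panel = clinstats.roc_panel(panel_features, labels, seed=seed)
        roc_records.append(panel.to_dict())
        panel_auc = panel.auc
    with open(outdir / "roc.json", "w", encoding="utf-8") as fh:
        json.dump(roc_records, fh, indent=1, sort_keys=True)

    # SRM verification arm
    measurements = syndata.simulate_srm_measurements(seed=seed)
    ratios = srmtools.quantify_srm(measurements)
    ratios.to_csv(outdir / "srm_ratios.tsv", sep="\t", index=False,
                  float_format="%.6g")
    srm_stats = srmtools.srm_group_compare(ratios)
    srm_stats.to_csv(outdir / "srm_stats.tsv", sep="\t", index=False,
                     float_format="%.6g")

    summary = {
        "seed": seed,
        "n_peptides_identified": len(quant),
        "exclusivity": partition.counts(),
        "n_quantified": len(normalized),
        "n_differential": len(diff_ids),
        "n_unmatched_locations": len(unmatched),
        "logo": logo_summary,
        "protease_ranking": ranking,
        "n_clinical_stringent": int(assoc["passes_stringent"].sum()),
        "panel_auc": panel_auc,
        "srm": srm_stats.to_dict(orient="records"),
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return summary
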