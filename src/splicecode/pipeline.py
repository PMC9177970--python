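"""End-to-end analysis pipeline over a configuration.

Stages: simulate (or load) inputs -> consensus scan -> positional and region
splicing-potential statistics -> codon-level splicing table and codon usage
-> exon-intron architecture -> peak-overlap randomization enrichment.  The
result is one JSON-serializable report bundle whose tables mirror the
classic summaries for this analysis: per-class region score summaries, a
loop codon-usage table, an exon-structure contingency, a split-enrichment
table, and one enrichment record per peak sample x padding.

Determinism: all randomness flows from ``config['seed']`` through a fixed
spawn order of child generators, so the same configuration produces
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .codon_usage import (
    HUMAN_LIKE_USAGE_PER1000,
    cai,
    codon_fragility,
    expected_cai,
    rscu,
    usage_bias_test,
)
from .exon_architecture import (
    chi2_contingency,
    count_motif_exons,
    donor_class,
    loop_to_splice_site_distances,
    map_splits,
    split_enrichment,
    split_position_clusters,
)
from .formats import GenomicIntervalSet, Interval, cds_to_bed
from .interval_enrichment import Workspace, bh_correct, enrichment_test, pad_annotations
from .motifs import EFHAND_LOOP_PATTERN, parse_prosite_pattern, scan_protein
from .splice_scores import (
    LoopWindow,
    build_codon_splicing_table,
    compare_groups,
    control_exon_background,
    dinucleotide_enrichment,
    positional_profile,
    region_mean,
)
from .synthetic import (
    SimulationConfig,
    simulate_control_exons,
    simulate_efhand_genes,
    simulate_hexamer_sets,
    simulate_peaks,
)

logger = logging.getLogger("splicecode")

# Reference two-codon fractions for the loop codon-usage bias tests (the
# human-like usage table expressed as GAC/(GAC+GAT) etc.).
_REFERENCE_FRACTIONS = {
    "D": HUMAN_LIKE_USAGE_PER1000["GAC"]
    / (HUMAN_LIKE_USAGE_PER1000["GAC"] + HUMAN_LIKE_USAGE_PER1000["GAT"]),
    "E": HUMAN_LIKE_USAGE_PER1000["GAG"]
    / (HUMAN_LIKE_USAGE_PER1000["GAG"] + HUMAN_LIKE_USAGE_PER1000["GAA"]),
    "N": HUMAN_LIKE_USAGE_PER1000["AAC"]
    / (HUMAN_LIKE_USAGE_PER1000["AAC"] + HUMAN_LIKE_USAGE_PER1000["AAT"]),
}


def default_config() -> dict:
    return {
        "seed": 0,
        "flank": 48,
        "pseudocount": 0.5,
        "coordinating_codons": [1, 3, 5, 9, 12],
        "n_sims": 10_000,
        "pads": [0, 3, 6, 9],
        "statistic": "NT_OVERLAP",
        "n_enriched_samples": 3,
        "n_null_samples": 3,
        "expected_cai_n": 500,
        "simulation": {},
    }


def _merge_config(config: dict | None) -> dict:
    cfg = default_config()
    for key, value in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown pipeline config key {key!r}")
        cfg[key] = value
    if cfg["n_sims"] < 100:
        raise ValueError("n_sims must be >= 100")
    return cfg


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _loop_regions(coordinating_codons: list[int]) -> dict[str, list[int]]:
    """Hexamer-start position sets in loop-core coordinates (loop nt 1 = 1).

    The 108-nt motif spans positions -35..72 around the 36-nt loop.
    """
    efl = list(range(1, 37))
    cr = [3 * (k - 1) + o for k in coordinating_codons for o in (1, 2, 3)]
    efm = list(range(-35, 73))
    roef = [p for p in efm if p not in set(efl)]
    return {"EFL": efl, "CR": sorted(cr), "EFM": efm, "ROEF": roef}


def _loop_windows(cds_by_gene: dict[str, str], motifs, motif_class: str,
                  flank: int) -> list[LoopWindow]:
    windows = []
    for motif in motifs:
        if motif.motif_class != motif_class:
            continue
        cds = cds_by_gene[motif.gene_id]
        left = min(flank, motif.loop_start - 1)
        right = min(flank, len(cds) - motif.loop_end)
        seq = cds[motif.loop_start - 1 - left : motif.loop_end + right]
        windows.append(LoopWindow(seq, left, motif.loop_length_nt))
    return windows


def compare_to_background(summaries, control) -> dict:
    """Per-region mean difference vs the control-exon background, with a
    two-sided t-test on the pooled hexamer scores.

    ``summaries`` is a list of :class:`RegionScoreSummary` carrying pooled
    values; ``control`` is the control-exon summary.  Significance is echoed
    at the 0.01 and 0.0001 levels.
    """
    deltas = {}
    for s in summaries:
        stat, p = compare_groups(
            {"region": list(s.values), "control": list(control.values)},
            test="t",
        )
        deltas[s.region_name] = {
            "delta_vs_control": s.mean_score - control.mean_score,
            "t_stat": stat,
            "p": p,
            "significant_0.01": bool(p == p and p < 0.01),
            "significant_0.0001": bool(p == p and p < 0.0001),
        }
    return deltas


def run_pipeline(config: dict | None = None) -> dict:
    """Run the full analysis and return the report bundle (a plain dict)."""
    cfg = _merge_config(config)
    seed = int(cfg["seed"])
    sim_dict = dict(cfg["simulation"])
    sim_dict.setdefault("seed", seed)
    sim_cfg = SimulationConfig.from_dict(sim_dict)

    ss = np.random.SeedSequence(seed)
    (seq_genes, seq_ctrl, seq_hex, seq_cai, seq_peaks,
     seq_enrich) = ss.spawn(6)

    # --- stage 1: inputs -------------------------------------------------
    proteins, cds_records, motifs, models = simulate_efhand_genes(
        sim_cfg, np.random.default_rng(seq_genes))
    control_exons = simulate_control_exons(
        sim_cfg, np.random.default_rng(seq_ctrl))
    ese, ess, hex_table = simulate_hexamer_sets(
        sim_cfg, np.random.default_rng(seq_hex))
    cds_by_gene = dict(cds_records)
    protein_by_gene = dict(proteins)

    # --- stage 2: consensus scan ----------------------------------------
    pattern = parse_prosite_pattern(EFHAND_LOOP_PATTERN)
    scan_recovered = 0
    n_scannable = 0
    for motif in motifs:
        if motif.motif_class != "CANONICAL":
            continue
        n_scannable += 1
        expected_aa_start = (motif.loop_start - 1) // 3 + 1
        if expected_aa_start in scan_protein(protein_by_gene[motif.gene_id],
                                             pattern):
            scan_recovered += 1
    scan_summary = {
        "pattern": EFHAND_LOOP_PATTERN,
        "n_canonical": n_scannable,
        "n_recovered_by_scan": scan_recovered,
    }

    # --- stage 3: splicing-potential profiles ---------------------------
    regions = _loop_regions(list(cfg["coordinating_codons"]))
    control = control_exon_background(control_exons, hex_table)
    per_class_summaries: dict[str, dict] = {}
    class_windows: dict[str, list[LoopWindow]] = {}
    for motif_class in ("CANONICAL", "NONCANONICAL", "S100"):
        windows = _loop_windows(cds_by_gene, motifs, motif_class, cfg["flank"])
        if not windows:
            logger.info("pipeline: class %s empty, skipped", motif_class)
            continue
        class_windows[motif_class] = windows
        use_regions = regions
        if motif_class == "S100":
            # 42-nt pseudoloop: the motif spans -35..78
            efl = list(range(1, 43))
            efm = list(range(-35, 79))
            use_regions = {
                "EFL": efl,
                "CR": regions["CR"],
                "EFM": efm,
                "ROEF": [p for p in efm if p not in set(efl)],
            }
        summaries = region_mean(windows, use_regions, hex_table)
        per_class_summaries[motif_class] = {
            "regions": {s.region_name: s.as_dict() for s in summaries},
            "vs_control": compare_to_background(summaries, control),
        }

    profile = positional_profile(class_windows["CANONICAL"], hex_table)
    keep = [i for i, p in enumerate(profile.positions) if -35 <= p <= 72]
    profile_dict = {
        "positions": [profile.positions[i] for i in keep],
        "mean_score": [float(profile.mean_score[i]) for i in keep],
        "ess_start_count": [int(profile.ess_start_count[i]) for i in keep],
        "n_seq": [int(profile.n_seq[i]) for i in keep],
    }

    # --- stage 4: codon-level tables -------------------------------------
    codon_table = build_codon_splicing_table(ese, ess, cfg["pseudocount"])
    dinuc = dinucleotide_enrichment(ese, ess)

    canonical_loops = [
        cds_by_gene[m.gene_id][m.loop_start - 1 : m.loop_end]
        for m in motifs if m.motif_class == "CANONICAL"
    ]
    position_counts: dict[int, dict[str, int]] = {k: {} for k in (1, 3, 5, 12)}
    all_loop_codons: dict[str, int] = {}
    for loop in canonical_loops:
        codons = [loop[i : i + 3] for i in range(0, len(loop), 3)]
        for c in codons:
            all_loop_codons[c] = all_loop_codons.get(c, 0) + 1
        for k in position_counts:
            c = codons[k - 1]
            position_counts[k][c] = position_counts[k].get(c, 0) + 1

    usage_rows = []
    for k, pair, aa in ((1, ("GAC", "GAT"), "D"), (12, ("GAG", "GAA"), "E")):
        n_major = position_counts[k].get(pair[0], 0)
        n_minor = position_counts[k].get(pair[1], 0)
        n = n_major + n_minor
        row = {
            "loop_codon": k,
            "codons": list(pair),
            "counts": [n_major, n_minor],
            "fraction_major": n_major / n if n else float("nan"),
            "reference_fraction": _REFERENCE_FRACTIONS[aa],
        }
        row["binomial_p"] = (
            usage_bias_test((n_major, n_minor), _REFERENCE_FRACTIONS[aa])
            if n else float("nan")
        )
        usage_rows.append(row)

    loop_usage = rscu(all_loop_codons)
    reference = rscu({c: v for c, v in HUMAN_LIKE_USAGE_PER1000.items()})
    rng_cai = np.random.default_rng(seq_cai)
    loop_cais = []
    exp_means = []
    for loop in canonical_loops:
        loop_cais.append(cai(loop, reference))
        res = expected_cai(loop, reference, int(cfg["expected_cai_n"]), rng_cai)
        exp_means.append(res["mean"])
    cai_stat, cai_p = compare_groups(
        {"observed": loop_cais, "expected": exp_means}, test="t")
    fragility = {c: codon_fragility(c) for c in sorted(all_loop_codons)
                 if c not in ("TAA", "TAG", "TGA")}

    codon_usage_summary = {
        "loop_codon_bias": usage_rows,
        "mean_loop_cai": float(np.mean(loop_cais)),
        "mean_expected_cai": float(np.mean(exp_means)),
        "cai_t_stat": cai_stat,
        "cai_p": cai_p,
        "loop_rscu": {c: loop_usage.rscu[c] for c in sorted(all_loop_codons)},
        "fragility": fragility,
    }

    # --- stage 5: exon architecture --------------------------------------
    _, contingency = count_motif_exons(models, motifs)
    table2 = [contingency.get("CANONICAL", [0, 0, 0]),
              contingency.get("NONCANONICAL", [0, 0, 0])]
    try:
        chi2, dof, chi2_p = chi2_contingency(table2)
    except ValueError:
        chi2, dof, chi2_p = float("nan"), 0, float("nan")

    events = map_splits(models, motifs)
    split_tables = {}
    for label, classes in (("canonical", {"CANONICAL"}),
                           ("noncanonical", {"NONCANONICAL"}),
                           ("both", {"CANONICAL", "NONCANONICAL"})):
        class_by_motif = {f"{m.gene_id}:{i}": m.motif_class
                          for i, m in enumerate(motifs)}
        sub = [e for e in events if class_by_motif[e.motif_id] in classes]
        if sub:
            split_tables[label] = split_enrichment(sub).as_dict()
    canonical_events = [e for e in events
                        if e.motif_id in {f"{m.gene_id}:{i}"
                                          for i, m in enumerate(motifs)
                                          if m.motif_class == "CANONICAL"}]
    n_cluster, c_cluster = split_position_clusters(canonical_events)
    distances = loop_to_splice_site_distances(models, motifs)
    donor_counts = {"GT": 0, "GC": 0, "OTHER": 0}
    for classes_list in donor_class(models).values():
        for d in classes_list:
            donor_counts[d] += 1

    exon_structure = {
        "contingency": {"CANONICAL": table2[0], "NONCANONICAL": table2[1]},
        "chi2": chi2, "dof": dof, "chi2_p": chi2_p,
        "split_enrichment": split_tables,
        "distinct_positions_n_cluster": n_cluster,
        "distinct_positions_c_cluster": c_cluster,
        "n_one_exon_loops_lt400": len(distances),
        "donor_dinucleotides": donor_counts,
    }

    # --- stage 6: peak-overlap enrichment --------------------------------
    workspace = Workspace(GenomicIntervalSet(
        [Interval(gene_id, 0, len(seq)) for gene_id, seq in cds_records]))
    loop_bed = GenomicIntervalSet([
        cds_to_bed(m.gene_id, m.loop_start, m.loop_end, name=f"loop{i}")
        for i, m in enumerate(motifs) if m.motif_class == "CANONICAL"
    ])
    rng_peaks = np.random.default_rng(seq_peaks)
    samples = []
    for i in range(int(cfg["n_enriched_samples"])):
        samples.append((f"enriched{i}", sim_cfg.peak_model.fold_in_motifs))
    for i in range(int(cfg["n_null_samples"])):
        samples.append((f"null{i}", 1.0))
    enrich_rng = np.random.default_rng(seq_enrich)
    runs = []
    for sample_id, fold in samples:
        peaks = simulate_peaks(sim_cfg, loop_bed, workspace, rng_peaks,
                               fold=fold, name_prefix=sample_id)
        for pad in cfg["pads"]:
            annotations = pad_annotations(loop_bed, int(pad), workspace)
            res = enrichment_test(
                peaks, annotations, workspace,
                n_sims=int(cfg["n_sims"]), seed=enrich_rng,
                statistic=cfg["statistic"],
                sample_id=f"{sample_id}_pad{pad}",
            )
            record = res.as_dict()
            record["pad"] = int(pad)
            record["programmed_fold"] = fold
            runs.append(record)
    q, flags = bh_correct([r["p_empirical"] for r in runs], alpha=0.01)
    for record, qv, flag in zip(runs, q, flags):
        record["q_bh"] = float(qv)
        record["significant_q01"] = bool(flag)

    bundle = {
        "provenance": {
            "tool": "splicecode",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(cfg),
        },
        "scan": scan_summary,
        "control_background": control.as_dict(),
        "per_class_region_summaries": per_class_summaries,
        "canonical_positional_profile": profile_dict,
        "codon_splicing_table": codon_table.as_rows(),
        "dinucleotide_log_odds": dinuc,
        "codon_usage": codon_usage_summary,
        "exon_structure": exon_structure,
        "enrichment_runs": runs,
    }
    return bundle


def write_report(bundle: dict, path: str | Path) -> None:
    """Serialize a report bundle deterministically (sorted keys, no
    timestamps)."""
    with open(path, "w") as handle:
        json.dump(bundle, handle, indent=2, sort_keys=True, allow_nan=True)
        handle.write("\n")
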