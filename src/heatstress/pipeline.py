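"""End-to-end orchestration of the synthetic heat-stress analysis chain.

``run_pipeline`` generates a synthetic study, runs every analysis stage in
dependency order, and writes one TSV per stage plus a provenance log
(config hash, seed, package version) into the output directory. Reruns with
the same configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

import heatstress
from heatstress import concord, de, enrich, io, itraq, som, supersat, synthetic


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return run

    return wrap


def truth_gene_sets(truth: synthetic.ExpressionTruth) -> enrich.GeneSetCollection:
    """Gene sets derived from planted truth, for exercising the ORA stage."""
    ids = synthetic.feature_ids(truth.n_features)
    consensus = frozenset(truth.consensus_fold_changes)
    half = len(ids) // 2
    sets = {
        "planted_consensus": consensus,
        "planted_node_up": frozenset(truth.node_up),
        "planted_node_down": frozenset(truth.node_down),
        "first_half_background": frozenset(ids[:half]),
    }
    descriptions = {name: "synthetic truth-derived set" for name in sets}
    return enrich.GeneSetCollection(sets=sets, descriptions=descriptions)


def run_pipeline(
    config: io.PipelineConfig,
    out_dir: str | Path,
    study_config: synthetic.StudyDesignConfig | None = None,
    expression_truth: synthetic.ExpressionTruth | None = None,
    proteome_truth: synthetic.ProteomeTruth | None = None,
) -> dict[str, Path]:
    """Run every stage on synthetic inputs and write stage outputs as TSV.

    Returns a mapping from stage name to output path. Any stage failure
    aborts with the stage name attached.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    study_config = study_config or synthetic.StudyDesignConfig(seed=config.seed)
    expression_truth = expression_truth or synthetic.default_expression_truth(
        study_config
    )
    proteome_truth = proteome_truth or synthetic.default_proteome_truth(
        seed=config.seed
    )

    # --- simulate ---------------------------------------------------------
    study = _stage("simulate")(synthetic.generate_expression_study)(
        study_config, expression_truth
    )
    io.write_expression_study(study, out / "expression.tsv", out / "design.tsv")
    outputs["expression"] = out / "expression.tsv"
    outputs["design"] = out / "design.tsv"

    peptides = _stage("simulate")(synthetic.generate_peptide_table)(
        proteome_truth, seed=config.seed
    )
    io.write_peptide_table(peptides, out / "peptides.csv")
    outputs["peptides"] = out / "peptides.csv"

    # --- differential expression and consensus ----------------------------
    tc_max = study_config.time_points[0]
    last = study_config.time_points[-1]
    de_tables: dict[str, pd.DataFrame] = {}
    retained: dict[str, pd.Index] = {}
    for organ in study_config.organs:
        sub = study.organ_subset(organ)
        keep = _stage("variance_filter")(de.variance_filter)(sub.values)
        retained[organ] = keep
        filtered = de.ExpressionStudy(sub.values.loc[keep], sub.design)
        records = _stage("de")(de.differential_expression)(
            filtered,
            organ,
            tc_max,
            fc_threshold=config.gene_fc_threshold,
            q_threshold=config.fdr_threshold,
        )
        de_tables[organ] = records
        io.write_table(records, out / f"de_{organ}_{tc_max}.tsv")
        outputs[f"de_{organ}"] = out / f"de_{organ}_{tc_max}.tsv"

    consensus = _stage("consensus")(de.consensus_intersection)(de_tables, tc_max)
    consensus_df = consensus.fold_changes.copy()
    consensus_df.index.name = "feature"
    io.write_table(consensus_df, out / "consensus.tsv")
    outputs["consensus"] = out / "consensus.tsv"

    # --- SOM anchoring on the heart at the last time point ----------------
    heart = study.organ_subset(study_config.organs[0])
    at_last = heart.design["time"] == last
    profiles = heart.values.loc[:, at_last.to_numpy()]
    zprofiles = som.zscore_profiles(profiles)
    params = som.SOMParams(
        epochs=config.som_epochs, learning_rate=config.som_learning_rate
    )
    model = _stage("som")(som.train_som)(
        zprofiles, grid=config.som_grid, params=params, seed=config.seed
    )
    assignment = som.assign_nodes(model, zprofiles)
    injured = heart.design.loc[at_last, "injured"].to_numpy()
    anchored = _stage("som")(som.anchor_nodes)(
        model, assignment, profiles, injured, threshold=config.anchor_threshold
    )
    node_table = pd.DataFrame(
        {
            "feature": assignment.index,
            "node": assignment.to_numpy(),
        }
    ).set_index("feature")
    io.write_table(node_table, out / "som_nodes.tsv")
    anchor_table = pd.DataFrame(
        [
            {
                "node": a.node,
                "direction": a.direction,
                "separation": a.separation,
                "n_members": len(a.members),
            }
            for a in anchored
        ]
    )
    io.write_table(anchor_table, out / "som_anchored.tsv", index=False)
    outputs["som_nodes"] = out / "som_nodes.tsv"
    outputs["som_anchored"] = out / "som_anchored.tsv"

    # --- ORA on the consensus set vs the variance-filtered background -----
    first_organ = study_config.organs[0]
    background = set(retained[first_organ])
    query = [f for f in consensus.features if f in background]
    collection = truth_gene_sets(expression_truth)
    ora = _stage("ora")(enrich.overrepresentation)(
        query,
        collection,
        background,
        max_term_size=config.ora_max_term_size,
        min_overlap=config.ora_min_overlap,
        min_es=config.ora_min_es,
        max_p=config.ora_max_p,
    )
    io.write_table(ora, out / "ora.tsv")
    outputs["ora"] = out / "ora.tsv"

    # --- iTRAQ quantitation ------------------------------------------------
    normalized = _stage("itraq")(itraq.normalize_reporters)(peptides)
    quant = _stage("itraq")(itraq.rollup_protein_ratios)(
        normalized, reference_channel=config.reference_channel
    )
    condition_channel = next(iter(proteome_truth.channel_conditions))
    fold = itraq.protein_fold_changes(
        quant, condition_channel, fc_threshold=config.protein_fc_threshold
    )
    io.write_table(fold, out / "protein_quant.tsv")
    outputs["protein_quant"] = out / "protein_quant.tsv"

    top3 = _stage("top3")(itraq.top3_abundance)(peptides)
    io.write_table(top3.to_frame(), out / "top3.tsv")
    outputs["top3"] = out / "top3.tsv"

    # --- supersaturation ----------------------------------------------------
    z_agg = pd.Series(dict(proteome_truth.z_agg), name="z_agg")
    calibrants = pd.Series(dict(proteome_truth.calibrants))
    model_cal = _stage("supersat")(supersat.fit_calibration)(top3, calibrants)
    conc = supersat.infer_concentrations(model_cal, top3)
    scores = _stage("supersat")(supersat.supersaturation_scores)(
        z_agg,
        conc,
        fold_changes=fold["fold_change"],
        changed_threshold=config.protein_fc_threshold,
        unchanged_threshold=config.unchanged_threshold,
        log_base=config.log_base,
    )
    io.write_table(scores, out / "supersaturation.tsv")
    outputs["supersaturation"] = out / "supersaturation.tsv"

    grouped = {
        label: scores.loc[scores["group"] == label, "sigma_f"].to_numpy()
        for label in (supersat.CHANGED, supersat.UNCHANGED)
    }
    comparison = _stage("supersat")(supersat.compare_groups)(grouped)
    summary = pd.DataFrame(
        {
            "group": list(comparison.means),
            "mean_sigma_f": [comparison.means[g] for g in comparison.means],
            "sem": [comparison.sems[g] for g in comparison.means],
            "n": [comparison.sizes[g] for g in comparison.means],
        }
    )
    summary["anova_f"] = comparison.f_statistic
    summary["anova_p"] = comparison.p_value
    io.write_table(summary, out / "supersaturation_groups.tsv", index=False)
    outputs["supersaturation_groups"] = out / "supersaturation_groups.tsv"

    # --- concordance --------------------------------------------------------
    heart_de = de_tables[first_organ].reset_index()
    heart_de["gene_symbol"] = heart_de["feature"]
    mapping = pd.DataFrame(
        {
            "protein": list(proteome_truth.protein_ids),
            # synthetic identity-style mapping onto planted consensus features
            "gene_symbol": [
                synthetic.feature_ids(expression_truth.n_features)[
                    i % expression_truth.n_features
                ]
                for i in range(len(proteome_truth.protein_ids))
            ],
        }
    )
    pairs = _stage("concordance")(concord.map_and_classify)(
        heart_de,
        fold,
        mapping,
        gene_fc_threshold=config.gene_fc_threshold,
        protein_fc_threshold=config.protein_fc_threshold,
    )
    io.write_table(pairs, out / "concordance.tsv", index=False)
    outputs["concordance"] = out / "concordance.tsv"

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": heatstress.__version__,
        "stages": sorted(outputs),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    outputs["provenance"] = out / "provenance.json"
    return outputs
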