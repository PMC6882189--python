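"""End-to-end orchestration: classify -> collapse -> network -> popgen -> PCA.

A single YAML config drives the full analysis; every stage writes plain
TSV/CSV/JSON artifacts into the output directory and the run ends with
a manifest listing each artifact with its SHA-256 hash, so reruns with
the same inputs and seed can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import motifs as motifs_mod
from . import network as network_mod
from . import pca as pca_mod
from . import popgen as popgen_mod
from .window import (
    ReferenceWindow,
    call_variants,
    collapse_haplotypes,
    haplotypes_to_dataframe,
    load_alignment,
    trim_to_window,
)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "window": {"start": 15494, "end": 15740},
    "alignment": {"offset": 15494},
    "classify": {"min_fraction": 0.5, "min_margin": 1e-9},
    "network": {"dominant_min": 40},
    "popgen": {"permutations": 10100, "seed": 42},
    "pca": {"standardization": "correlation", "cases": "haplogroups",
            "level": "population"},
}


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return config


def _merged(config: dict) -> dict:
    merged = {k: dict(v) for k, v in DEFAULTS.items()}
    for key, value in config.items():
        if key in merged and isinstance(value, dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def validate_config(config: dict) -> dict:
    config = _merged(config)
    inputs = config.get("inputs", {})
    for key in ("fasta", "metadata", "reference_fasta"):
        path = inputs.get(key)
        if path is None:
            raise ValueError(f"config inputs.{key} is required")
        if not Path(path).exists():
            raise ValueError(f"config inputs.{key}: file not found: {path}")
    motifs_path = inputs.get("motifs")
    labels_path = inputs.get("training_labels")
    if motifs_path is None and labels_path is None:
        raise ValueError("config needs inputs.motifs (JSON) or "
                         "inputs.training_labels (TSV) to obtain motifs")
    for key, path in (("motifs", motifs_path), ("training_labels", labels_path)):
        if path is not None and not Path(path).exists():
            raise ValueError(f"config inputs.{key}: file not found: {path}")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    inputs = config["inputs"]
    window = ReferenceWindow.from_fasta(
        inputs["reference_fasta"],
        start_pos=int(config["window"]["start"]),
        end_pos=int(config["window"]["end"]),
    )
    offset = int(config["alignment"]["offset"])

    # --- stage: load + variant profiles -------------------------------
    pairs = load_alignment(inputs["fasta"], inputs["metadata"])
    records = [rec for rec, _seq in pairs]
    profiles = [
        call_variants(trim_to_window(seq, window, offset), window, rec.sample_id)
        for rec, seq in pairs
    ]
    logger.info("stage=profiles samples_in=%d profiles_out=%d", len(pairs), len(profiles))
    profiles_path = outdir / "variant_profiles.tsv"
    pd.DataFrame(
        [{"sample_id": p.sample_id, "variants": p.canonical_key} for p in profiles]
    ).to_csv(profiles_path, sep="\t", index=False)
    artifacts["variant_profiles"] = profiles_path

    # --- stage: motifs -------------------------------------------------
    if inputs.get("motifs"):
        motif_list = motifs_mod.motifs_from_json(inputs["motifs"])
    else:
        labels = pd.read_csv(inputs["training_labels"], sep="\t", dtype=str)
        label_of = dict(zip(labels["sample_id"], labels["haplogroup"]))
        labelled = [(p, label_of[p.sample_id]) for p in profiles
                    if p.sample_id in label_of]
        motif_list = motifs_mod.infer_motifs(labelled, window=window)
    motifs_path = outdir / "motifs.json"
    motifs_mod.motifs_to_json(motif_list, motifs_path)
    artifacts["motifs"] = motifs_path

    # --- stage: classification ----------------------------------------
    classify_cfg = config["classify"]
    calls, summary = motifs_mod.classify_dataset(
        profiles, motif_list, records,
        min_fraction=float(classify_cfg["min_fraction"]),
        min_margin=float(classify_cfg["min_margin"]),
    )
    logger.info("stage=classify samples_in=%d unclassified=%d", len(calls),
                sum(c.haplogroup == motifs_mod.UNCLASSIFIED for c in calls))
    calls_path = outdir / "haplogroup_calls.tsv"
    motifs_mod.calls_to_dataframe(calls).to_csv(calls_path, sep="\t", index=False,
                                                float_format="%.6f")
    summary_path = outdir / "haplogroup_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    artifacts["haplogroup_calls"] = calls_path
    artifacts["haplogroup_summary"] = summary_path

    # --- stage: haplotype table + network ------------------------------
    call_of = {c.sample_id: c.haplogroup for c in calls}
    haplotypes = collapse_haplotypes(profiles, records, haplogroups=call_of)
    haplotypes_path = outdir / "haplotypes.tsv"
    haplotypes_to_dataframe(haplotypes).to_csv(haplotypes_path, sep="\t", index=False)
    artifacts["haplotypes"] = haplotypes_path

    net = network_mod.build_mst(haplotypes)
    for name, path in network_mod.write_network(net, outdir).items():
        artifacts[f"network_{name}"] = path
    logger.info("stage=network nodes=%d edges=%d weight=%d",
                len(net.nodes), len(net.edges), net.total_weight)

    cohorts = config.get("cohorts")
    if cohorts:
        fstats = network_mod.unique_haplotype_stats(haplotypes, cohorts)
        fstats_path = outdir / "f_percent.tsv"
        fstats.to_csv(fstats_path, sep="\t", index=False, float_format="%.4f")
        artifacts["f_percent"] = fstats_path
    dominant = network_mod.dominant_haplotypes(
        haplotypes, int(config["network"]["dominant_min"]))
    dominant_path = outdir / "dominant_haplotypes.tsv"
    haplotypes_to_dataframe(dominant).to_csv(dominant_path, sep="\t", index=False)
    artifacts["dominant_haplotypes"] = dominant_path

    # --- stage: popgen --------------------------------------------------
    popgen_cfg = config["popgen"]
    seed = int(popgen_cfg["seed"])
    by_pop: dict[str, list] = {}
    for p, rec in zip(profiles, records):
        by_pop.setdefault(rec.population, []).append(p)
    pops = [popgen_mod.PopulationSample(name, prof)
            for name, prof in sorted(by_pop.items())]

    if cohorts:
        region_to_cohort = {r: c for c, regions in cohorts.items() for r in regions}
        pop_region = {rec.population: rec.region for rec in records}
        group_assignment = {p.population: region_to_cohort[pop_region[p.population]]
                            for p in pops}
        amova_result = popgen_mod.amova(
            pops, group_assignment,
            n_permutations=int(popgen_cfg["permutations"]), seed=seed)
        amova_json = outdir / "amova.json"
        _json_dump(amova_result.to_json_dict(), amova_json)
        amova_txt = outdir / "amova.txt"
        amova_txt.write_text(amova_result.to_text() + "\n")
        artifacts["amova"] = amova_json
        artifacts["amova_text"] = amova_txt

        cohort_names = sorted(cohorts)
        if len(cohort_names) == 2:
            ca, cb = cohort_names
            members_a = [c for c, rec in zip(calls, records)
                         if region_to_cohort[rec.region] == ca]
            members_b = [c for c, rec in zip(calls, records)
                         if region_to_cohort[rec.region] == cb]
            rows = []
            hgs = sorted({c.haplogroup for c in calls
                          if c.haplogroup != motifs_mod.UNCLASSIFIED})
            for hg in hgs:
                res = popgen_mod.chi2_cohort_test(
                    (sum(c.haplogroup == hg for c in members_a),
                     sum(c.haplogroup == hg for c in members_b)),
                    (len(members_a), len(members_b)), haplogroup=hg)
                rows.append({"haplogroup": hg, "cohorts": f"{ca} vs {cb}",
                             "statistic": res.statistic, "p_value": res.p_value,
                             "low_expected": res.low_expected})
            chi2_path = outdir / "chi2_cohort_tests.tsv"
            pd.DataFrame(rows).to_csv(chi2_path, sep="\t", index=False,
                                      float_format="%.6g")
            artifacts["chi2"] = chi2_path

    # pairwise Phi_ST / Nm matrices over populations with n >= 2
    usable = [p for p in pops if p.n >= 2]
    if len(usable) >= 2:
        names = [p.population for p in usable]
        phi = pd.DataFrame(0.0, index=names, columns=names)
        nm = pd.DataFrame(float("inf"), index=names, columns=names)
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                v = popgen_mod.pairwise_phist(usable[i], usable[j])
                phi.iloc[i, j] = phi.iloc[j, i] = v
                nm.iloc[i, j] = nm.iloc[j, i] = popgen_mod.nm_from_phist(v)
        phi_path = outdir / "pairwise_phist.tsv"
        nm_path = outdir / "pairwise_nm.tsv"
        phi.to_csv(phi_path, sep="\t", float_format="%.6f")
        nm.to_csv(nm_path, sep="\t", float_format="%.6f")
        artifacts["pairwise_phist"] = phi_path
        artifacts["pairwise_nm"] = nm_path

    # --- stage: PCA ------------------------------------------------------
    pca_cfg = config["pca"]
    freq_table = pca_mod.build_frequency_table(calls, records,
                                               level=pca_cfg["level"])
    freq_path = outdir / "frequency_table.csv"
    freq_table.to_csv(freq_path)
    artifacts["frequency_table"] = freq_path
    try:
        pca_result = pca_mod.run_pca(freq_table,
                                     standardization=pca_cfg["standardization"],
                                     cases=pca_cfg["cases"])
    except ValueError as exc:
        logger.warning("stage=pca skipped: %s", exc)
        pca_result = None
    if pca_result is not None:
        pca_json = outdir / "pca.json"
        _json_dump(pca_result.to_json_dict(), pca_json)
        scores_path = outdir / "pca_scores.csv"
        scores = pd.DataFrame(pca_result.scores, index=pca_result.case_labels)
        scores.columns = [f"PC{i + 1}" for i in range(scores.shape[1])]
        scores.to_csv(scores_path, float_format="%.6f")
        artifacts["pca"] = pca_json
        artifacts["pca_scores"] = scores_path

    # --- truth accuracy report (when simulation truth is available) ------
    truth_path = inputs.get("truth")
    if truth_path and Path(truth_path).exists():
        truth = pd.read_csv(truth_path, sep="\t", dtype=str)
        truth_of = dict(zip(truth["sample_id"], truth["haplogroup"]))
        scored = [c for c in calls if c.sample_id in truth_of]
        correct = sum(c.haplogroup == truth_of[c.sample_id] for c in scored)
        report = {
            "n_samples": len(scored),
            "n_correct": correct,
            "accuracy": correct / len(scored) if scored else float("nan"),
            "n_unclassified": sum(c.haplogroup == motifs_mod.UNCLASSIFIED
                                  for c in scored),
        }
        accuracy_path = outdir / "truth_accuracy.json"
        _json_dump(report, accuracy_path)
        artifacts["truth_accuracy"] = accuracy_path

    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "artifacts": {
            name: {"path": path.name, "sha256": _sha256(path),
                   "bytes": path.stat().st_size}
            for name, path in sorted(artifacts.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    _json_dump(manifest, manifest_path)
    return manifest
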