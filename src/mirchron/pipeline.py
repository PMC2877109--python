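"""End-to-end orchestration: qPCR → filter → cluster → correlate → classify.

``run_pipeline`` executes the stages in order on a directory of input
TSVs, writes one table per stage plus a MANIFEST, and returns (and saves)
a JSON report of every headline count: dynamic features per layer, pair
counts per sign, direct targets per layer, regulation-mode fractions,
cluster sizes, and genomic clusters.  The run is fully deterministic for
a given configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import core_model as cm
from . import dynamic_filter as dyn
from . import protein_integration as prot
from . import qpcr_preprocess as qpcr
from . import regulation_classify as reg
from . import temporal_clustering as clus
from .correlation_targets import correlate_all_pairs, intersect_predictions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths and every tunable threshold of the pipeline.

    Threshold defaults are the published operating point: CT ceiling 35,
    U6 reference, mRNA Max > 7 / Range > 1.2, miRNA Min ΔCT < 10 /
    Range > 2.2, q < 0.05, |r| > 0.9 (mRNA) and > 0.8 (protein), k = 6
    mRNA / 5 miRNA temporal patterns, genomic window 1 Mb with ≥ 3
    members.
    """

    ct_path: str = ""
    sample_sheet: str = ""
    mrna_path: str = ""
    protein_path: str = ""
    predictions_path: str = ""
    tx_idmap_path: str = ""
    protein_idmap_path: str = ""
    probe_gene_path: str = ""
    loci_path: str = ""
    second_mrna_list: str = ""  # optional EDGE-style comparison list
    second_mirna_list: str = ""

    ct_ceiling: float = 35.0
    reference_assay: str = "U6"
    mrna_max_cutoff: float = 7.0
    mrna_range_cutoff: float = 1.2
    mirna_min_cutoff: float = 10.0
    mirna_range_cutoff: float = 2.2
    q_cutoff: float = 0.05
    r_cutoff_mrna: float = 0.9
    r_cutoff_protein: float = 0.8
    k_mrna: int = 6
    k_mirna: int = 5
    genomic_window: int = 1_000_000
    genomic_min_members: int = 3
    protein_aggregate: str = "sum"
    protein_pseudocount: float = 1.0
    mirna_orientation: str = "expression"  # correlate −ΔCT ("expression") or raw ΔCT ("dct")

    seed: int = 0
    outdir: str = "mirchron_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def mrna_thresholds(self) -> cm.FilterThresholds:
        return cm.FilterThresholds(
            "mRNA", "max_above", self.mrna_max_cutoff, self.mrna_range_cutoff, self.q_cutoff
        )

    def mirna_thresholds(self) -> cm.FilterThresholds:
        return cm.FilterThresholds(
            "miRNA", "min_below", self.mirna_min_cutoff, self.mirna_range_cutoff, self.q_cutoff
        )


def _read_list(path: str) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def analyze_bundle(bundle, r_cutoff_mrna: float = 0.9, r_cutoff_protein: float = 0.8):
    """Run the analysis stages in memory on a synthetic bundle.

    Convenience for simulation studies: qPCR preprocessing, dynamic
    filters at the default thresholds, both correlation screens, and
    regulation classification.  Returns (calls, summary, mrna_pairs,
    protein_pairs).
    """
    censored = qpcr.censor_ct(bundle.ct)
    dct = qpcr.delta_ct(censored, design=bundle.design)
    expr = qpcr.dct_to_log2_expression(dct)
    mirna_pass, _ = dyn.dynamic_features(dct, cm.MIRNA_THRESHOLDS)
    mrna_pass, _ = dyn.dynamic_features(bundle.mrna, cm.MRNA_THRESHOLDS)
    dyn_expr = cm.ExpressionMatrix(
        "miRNA", expr.values.loc[mirna_pass], expr.design, "expression"
    )
    dyn_mrna = cm.ExpressionMatrix(
        "mRNA", bundle.mrna.values.loc[mrna_pass], bundle.mrna.design
    )
    pairs = correlate_all_pairs(dyn_expr, dyn_mrna, cutoff=r_cutoff_mrna)
    pairs = intersect_predictions(
        pairs, bundle.predictions, prediction_idmap=bundle.tx_to_probe
    )
    protein_em = prot.merge_fractions(bundle.protein_table, design=bundle.design)
    protein_pairs = prot.protein_correlation_targets(
        dyn_expr, protein_em, cutoff=r_cutoff_protein,
        predictions=bundle.predictions, prediction_idmap=bundle.tx_to_probe,
        protein_idmap=bundle.protein_to_probe,
    )
    calls = reg.classify_regulation(
        pairs, protein_pairs, mrna_pass,
        probe_to_gene=bundle.probe_to_gene, protein_idmap=bundle.protein_to_probe,
    )
    return calls, reg.summarize_modes(calls), pairs, protein_pairs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the machine-readable run report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"config": asdict(cfg), "stages": {}}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        manifest.append(name)

    stage = "qpcr"
    try:
        sheet = cm.read_sample_sheet(cfg.sample_sheet)
        raw_ct = cm.read_ct_matrix(cfg.ct_path, reference_assay=cfg.reference_assay)
        qcfg = qpcr.QpcrConfig(ct_ceiling=cfg.ct_ceiling, reference_assay=cfg.reference_assay)
        censored = qpcr.censor_ct(raw_ct, qcfg)
        design = cm.TimeCourseDesign().with_samples(sheet)
        dct = qpcr.delta_ct(censored, qcfg, design=design)
        mirna_expr = qpcr.dct_to_log2_expression(dct)
        copies = qpcr.copies_table(censored, qcfg)
        save(dct.values, "delta_ct.tsv", index_label="mirna")
        save(mirna_expr.values, "mirna_expression.tsv", index_label="mirna")
        save(copies, "copies_per_cell.tsv", index_label="mirna")
        report["stages"][stage] = {
            "n_mirna": int(dct.values.shape[0]), "n_samples": int(dct.values.shape[1])
        }

        stage = "filter_mirna"
        mirna_pass, mirna_stats = dyn.dynamic_features(dct, cfg.mirna_thresholds())
        save(mirna_stats, "mirna_stats.tsv", index_label="mirna")
        (out / "dynamic_mirnas.txt").write_text("\n".join(mirna_pass) + "\n")
        manifest.append("dynamic_mirnas.txt")
        report["stages"][stage] = {"n_tested": len(mirna_stats), "n_dynamic": len(mirna_pass)}
        if cfg.second_mirna_list:
            ov = dyn.overlap_report(mirna_pass, _read_list(cfg.second_mirna_list))
            report["stages"][stage]["second_method_overlap"] = ov

        stage = "filter_mrna"
        mrna = cm.read_expression_matrix(cfg.mrna_path, "mRNA", sheet)
        mrna_pass, mrna_stats = dyn.dynamic_features(mrna, cfg.mrna_thresholds())
        save(mrna_stats, "mrna_stats.tsv", index_label="probe")
        (out / "dynamic_probes.txt").write_text("\n".join(mrna_pass) + "\n")
        manifest.append("dynamic_probes.txt")
        report["stages"][stage] = {"n_tested": len(mrna_stats), "n_dynamic": len(mrna_pass)}
        if cfg.second_mrna_list:
            ov = dyn.overlap_report(mrna_pass, _read_list(cfg.second_mrna_list))
            report["stages"][stage]["second_method_overlap"] = ov

        stage = "cluster"
        report["stages"][stage] = {}
        for label, em, ids, k in (
            ("mirna", mirna_expr, mirna_pass, cfg.k_mirna),
            ("mrna", mrna, mrna_pass, cfg.k_mrna),
        ):
            if len(ids) < k:
                logger.warning("%s: only %d dynamic features, skipping clustering", label, len(ids))
                report["stages"][stage][label] = {"skipped": True, "n_dynamic": len(ids)}
                continue
            sub = cm.ExpressionMatrix(
                em.layer, em.values.loc[ids], em.design, em.orientation
            )
            result = clus.cluster_temporal(sub, k=k)
            frame = result.assignments.to_frame()
            frame["pattern"] = frame["cluster"].map(result.labels)
            save(frame, f"clusters_{label}.tsv", index_label="feature")
            save(result.centroids, f"centroids_{label}.tsv", index_label="cluster")
            report["stages"][stage][label] = {
                "sizes": {int(c): int(n) for c, n in result.sizes().items()},
                "patterns": result.labels,
            }

        stage = "correlate"
        predictions = cm.load_prediction_table(cfg.predictions_path)
        tx_idmap = cm.load_idmap(cfg.tx_idmap_path)
        dyn_mirna_expr = cm.ExpressionMatrix(
            "miRNA", mirna_expr.values.loc[mirna_pass], mirna_expr.design, "expression"
        )
        if cfg.mirna_orientation == "dct":
            logger.info("correlating on raw ΔCT orientation as configured")
            dyn_mirna_expr = cm.ExpressionMatrix(
                "miRNA", -dyn_mirna_expr.values, mirna_expr.design, "expression"
            )
        dyn_mrna = cm.ExpressionMatrix("mRNA", mrna.values.loc[mrna_pass], mrna.design)
        pairs = correlate_all_pairs(dyn_mirna_expr, dyn_mrna, cutoff=cfg.r_cutoff_mrna)
        pairs = intersect_predictions(pairs, predictions, prediction_idmap=tx_idmap)
        save(pairs, "mrna_pairs.tsv", index=False)
        report["stages"][stage] = {
            "n_negative": int((pairs["direction"] == "negative").sum()),
            "n_positive": int((pairs["direction"] == "positive").sum()),
            "n_direct": int(pairs["direct"].sum()),
            "n_mirna_with_direct": int(pairs.loc[pairs["direct"], "mirna"].nunique()),
        }

        stage = "protein"
        protein_pairs = pd.DataFrame(columns=[*pairs.columns])
        if cfg.protein_path:
            table = prot.read_protein_table(cfg.protein_path)
            protein_em = prot.merge_fractions(
                table, design=dyn_mirna_expr.design,
                aggregate=cfg.protein_aggregate, pseudocount=cfg.protein_pseudocount,
            )
            protein_idmap = cm.load_idmap(cfg.protein_idmap_path)
            protein_pairs = prot.protein_correlation_targets(
                dyn_mirna_expr, protein_em, cutoff=cfg.r_cutoff_protein,
                predictions=predictions, prediction_idmap=tx_idmap,
                protein_idmap=protein_idmap,
            )
            save(protein_pairs, "protein_pairs.tsv", index=False)
            report["stages"][stage] = {
                "n_proteins": int(protein_em.values.shape[0]),
                "n_negative": int((protein_pairs["direction"] == "negative").sum()),
                "n_positive": int((protein_pairs["direction"] == "positive").sum()),
                "n_direct": int(protein_pairs["direct"].sum()),
            }
        else:
            report["stages"][stage] = {"skipped": True}
            protein_idmap = None

        stage = "classify"
        probe_to_gene = {}
        if cfg.probe_gene_path:
            pg = pd.read_csv(cfg.probe_gene_path, sep="\t", dtype=str)
            probe_to_gene = dict(zip(pg.iloc[:, 0], pg.iloc[:, 1]))
        calls = reg.classify_regulation(
            pairs, protein_pairs, mrna_pass,
            probe_to_gene=probe_to_gene, protein_idmap=protein_idmap,
        )
        save(calls, "regulation_calls.tsv", index=False)
        summary = reg.summarize_modes(calls)
        report["stages"][stage] = summary

        stage = "gclusters"
        if cfg.loci_path:
            loci = cm.read_loci(cfg.loci_path)
            gclusters = reg.genomic_cluster_mirnas(
                loci, window=cfg.genomic_window, min_members=cfg.genomic_min_members
            )
            gframe = pd.DataFrame(
                [
                    {
                        "cluster_id": c.cluster_id, "chrom": c.chrom,
                        "members": ";".join(c.members), "n_members": len(c.members),
                        "span": c.span,
                    }
                    for c in gclusters
                ]
            )
            save(gframe, "genomic_clusters.tsv", index=False)
            report["stages"][stage] = {
                "n_clusters": len(gclusters),
                "sizes": [len(c.members) for c in gclusters],
            }
        else:
            report["stages"][stage] = {"skipped": True}
    except Exception as exc:
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "MANIFEST").write_text("\n".join(manifest + ["report.json"]) + "\n")
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report
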