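"""End-to-end runner: mine -> prioritize -> pathway-score.

Writes four artifacts under ``config.outdir``:

* ``signature_records.tsv`` — nominal/adjusted/empirical p per random signature
* ``selected_signatures.gmt`` — the significant random signatures
* ``gene_calls.tsv`` — raw, diffusion and permutation score per called gene
* ``pathway_scores.tsv`` — per-pathway gene counts and separation p-values

plus ``manifest.json`` recording the config hash, per-stage seeds and
timings, and input checksums.  A stage failure aborts with the stage name;
artifacts written up to that point are flagged incomplete in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time as _time

import networkx as nx
import numpy as np
import pandas as pd

from . import io_formats as io
from . import network_prioritization as netp
from . import pathway_analysis as pa
from . import random_mining as mining
from .config import PipelineConfig, stage_seed

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "phenotype_from_events"]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def phenotype_from_events(cohort: io.SurvivalCohort) -> np.ndarray:
    """Good/poor phenotype labels from the event indicator.

    Patients with an observed event are the poor-prognosis phenotype ~N;
    censored patients are the good-prognosis phenotype N.
    """
    return np.where(np.asarray(cohort.event) == 1, pa.POOR, pa.GOOD)


def run_pipeline(config: PipelineConfig) -> dict:
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "config": json.loads(json.dumps(config.__dict__, default=str)),
        "config_digest": config.digest(),
        "stages": {},
        "inputs": {},
        "complete": False,
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")

    def flush() -> None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    stage = "load"
    try:
        t0 = _time.perf_counter()
        for key in ("expression", "survival", "templates", "network"):
            path = getattr(config, key)
            if not path:
                raise ValueError(f"config field {key!r} is required")
            if not os.path.exists(path):
                raise FileNotFoundError(f"config field {key!r}: no such file {path!r}")
            manifest["inputs"][key] = _checksum(path)
        if config.pathways:
            manifest["inputs"]["pathways"] = _checksum(config.pathways)
        cohort = io.attach_survival(
            io.read_expression(config.expression), io.read_survival(config.survival)
        )
        templates = io.read_gmt(config.templates)
        network = io.read_string_edges(config.network)
        pathways = io.read_gmt(config.pathways) if config.pathways else None
        manifest["stages"][stage] = {"seconds": round(_time.perf_counter() - t0, 3)}

        # ------------------------------------------------------------------
        stage = "mine"
        t0 = _time.perf_counter()
        seed = stage_seed(config.seed, stage)
        manifest["stages"][stage] = {"seed": seed}
        batches = []
        for k, (name, genes) in enumerate(templates.items()):
            batch = mining.generate_random_signatures(
                universe=cohort.gene_ids,
                size=min(len(genes), cohort.n_genes),
                n=config.n_random_per_template,
                seed=mining.derive_seed(seed, 2 * k),
                template_name=name,
            )
            mining.evaluate_batch(
                batch, cohort, n_perm=config.n_perm_signature,
                seed=mining.derive_seed(seed, 2 * k + 1),
            )
            batches.append(batch)
        selected = mining.select_significant(
            batches,
            empirical_threshold=config.empirical_threshold,
            log10_nominal_threshold=config.log10_nominal_threshold,
        )
        records = pd.DataFrame(
            [
                {
                    "signature": r.signature_name,
                    "template": b.template_name,
                    "size": b.size,
                    "nominal_p": r.nominal_p,
                    "adjusted_p": r.adjusted_p,
                    "empirical_p": r.empirical_p,
                    "n_perm": r.n_perm,
                }
                for b in batches
                for r in b.records
            ]
        )
        records.to_csv(os.path.join(config.outdir, "signature_records.tsv"), sep="\t", index=False)
        io.write_gmt(
            io.GeneSetCollection(
                sets={name: genes for name, genes in selected},
                descriptions={name: "significant random signature" for name, _ in selected},
            ),
            os.path.join(config.outdir, "selected_signatures.gmt"),
        )
        logger.info("mine: %d/%d signatures selected", len(selected), len(records))
        manifest["stages"][stage].update(
            seconds=round(_time.perf_counter() - t0, 3),
            n_signatures=int(len(records)),
            n_selected=int(len(selected)),
        )

        # ------------------------------------------------------------------
        stage = "prioritize"
        t0 = _time.perf_counter()
        seed = stage_seed(config.seed, stage)
        cohort_genes = set(cohort.gene_ids)
        subgraph = nx.Graph(
            (u, v, d)
            for u, v, d in network.graph.edges(data=True)
            if u in cohort_genes and v in cohort_genes
        )
        dropped = network.n_edges - subgraph.number_of_edges()
        if dropped:
            logger.info("prioritize: dropped %d network edges outside the cohort", dropped)
        raw = netp.occurrence_scores(selected, cohort.gene_ids)
        laplacian = netp.build_laplacian(io.WeightedNetwork(subgraph), cohort.gene_ids)
        operator = netp.diffusion_kernel(laplacian, config.beta, gene_ids=cohort.gene_ids)
        diffused = netp.diffuse(operator, raw)
        perm_scores = netp.permutation_scores(
            operator, raw, n_perm=config.n_perm_diffusion, seed=seed,
            null_mode=config.null_mode,
        )
        calls = netp.call_significant_genes(
            cohort.gene_ids, raw.values, diffused.values, perm_scores, alpha=config.alpha
        )
        calls_df = pd.DataFrame(
            [
                {
                    "gene": c.gene_id,
                    "raw_score": c.raw_score,
                    "diffusion_score": c.diffusion_score,
                    "permutation_score": c.permutation_score,
                    "rank": c.rank,
                }
                for c in calls
            ],
            columns=["gene", "raw_score", "diffusion_score", "permutation_score", "rank"],
        )
        calls_df.to_csv(os.path.join(config.outdir, "gene_calls.tsv"), sep="\t", index=False)
        logger.info("prioritize: %d genes called significant", len(calls))
        manifest["stages"][stage] = {
            "seed": seed,
            "seconds": round(_time.perf_counter() - t0, 3),
            "n_called": int(len(calls)),
        }
        scores_df = pd.DataFrame(
            {
                "gene": cohort.gene_ids,
                "raw_score": raw.values,
                "diffusion_score": diffused.values,
                "permutation_score": perm_scores,
            }
        )

        # ------------------------------------------------------------------
        stage = "pathway-score"
        t0 = _time.perf_counter()
        rows = []
        if pathways is not None and len(calls):
            labels = phenotype_from_events(cohort)
            sg = [c.gene_id for c in calls]
            for name, genes in pathways.items():
                try:
                    table = pa.patient_pathway_scores(
                        cohort, labels, sg, genes, pathway_name=name
                    )
                except ValueError as exc:
                    logger.warning("pathway %s skipped: %s", name, exc)
                    continue
                p = pa.pathway_separation_test(table)
                rows.append(
                    {"pathway": name, "n_genes_in_SG": table.n_genes, "p_value": p}
                )
        pd.DataFrame(rows, columns=["pathway", "n_genes_in_SG", "p_value"]).to_csv(
            os.path.join(config.outdir, "pathway_scores.tsv"), sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "seconds": round(_time.perf_counter() - t0, 3),
            "n_pathways_scored": len(rows),
        }
        manifest["complete"] = True
        flush()
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        flush()
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    return {
        "manifest": manifest,
        "records": records,
        "selected": selected,
        "calls": calls_df,
        "scores": scores_df,
        "pathways": pd.DataFrame(rows, columns=["pathway", "n_genes_in_SG", "p_value"]),
        "cohort": cohort,
    }
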