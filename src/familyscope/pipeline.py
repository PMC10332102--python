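"""End-to-end pipeline: simulate -> identify -> tree/clans -> Ka/Ks -> DEG/networks -> qPCR.

``run_all`` executes every stage from a single flat configuration, writes
all artifacts under the configured output directory, and returns a
manifest with the counts at each filter.  Stage outputs are cached by a
hash of the stage-relevant parameters: a rerun with an unchanged
configuration skips clean stages and the manifest hash is identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_analysis as ea
from . import family_identification as fi
from . import phylogeny as ph
from . import qpcr_analysis as qa
from . import selection_analysis as sa
from . import synthetic_data as sd
from .io_formats import (
    Config,
    SequenceSet,
    TabularMatrix,
    read_fasta,
    read_matrix_tsv,
    validate_config,
    write_edgelist,
    write_fasta,
    write_matrix_tsv,
    write_newick,
)

logger = logging.getLogger("familyscope")

PATHWAY_DOMAIN_ID = "PF_PATHWAY"


@dataclass
class PipelineManifest:
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    @property
    def manifest_hash(self) -> str:
        # cache state is volatile across reruns and excluded from the hash
        stable = {
            name: {k: v for k, v in stage.items() if k != "cached"}
            for name, stage in self.stages.items()
        }
        payload = json.dumps(
            {"seed": self.seed, "stages": stable}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "stages": self.stages,
                "manifest_hash": self.manifest_hash,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _StageCache:
    def __init__(self, outdir: Path):
        self.path = outdir / ".stage_hashes.json"
        self.hashes = (
            json.loads(self.path.read_text()) if self.path.exists() else {}
        )

    def clean(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        return self.hashes.get(stage) == digest and all(p.exists() for p in outputs)

    def update(self, stage: str, digest: str) -> None:
        self.hashes[stage] = digest
        self.path.write_text(json.dumps(self.hashes, indent=2, sort_keys=True))


def run_all(config: Config | dict) -> PipelineManifest:
    """Run the complete synthetic-data pipeline described by ``config``."""
    cfg = config if isinstance(config, Config) else validate_config(config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(outdir)
    manifest = PipelineManifest(seed=seed)
    seeds = {
        name: int(s.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, s in zip(
            ["simulate", "expression", "ct", "pairs", "tree"],
            np.random.SeedSequence(seed).spawn(5),
        )
    }

    # --- stage: simulate -----------------------------------------------------
    sim_params = {
        k: cfg[k]
        for k in (
            "n_erf", "n_dreb", "n_ap2", "n_rav", "n_negative", "n_incomplete",
            "clan_mutation_rate", "n_pairs", "pair_omega", "pair_ds",
            "pair_codons", "expression", "expression_groups", "n_replicates",
            "n_expression_genes", "n_de_genes", "de_fold", "expr_sigma",
            "n_modules", "module_size", "module_loading", "n_pathway_genes",
            "qpcr", "qpcr_treatments", "qpcr_genes", "qpcr_fold",
        )
    }
    sim_params["seed"] = seed
    sim_digest = _params_hash(sim_params)
    paths = {
        "cds": outdir / "cds.fasta",
        "proteins": outdir / "proteins.fasta",
        "references": outdir / "references.fasta",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "truth_modules": outdir / "truth_modules.tsv",
        "ct": outdir / "ct.tsv",
    }
    sim_outputs = [paths["cds"], paths["proteins"], paths["references"],
                   paths["truth_genes"], paths["truth_pairs"]]
    cached = cache.clean("simulate", sim_digest, sim_outputs)
    if cached:
        cds = read_fasta(paths["cds"], "nucleotide")
        proteins = read_fasta(paths["proteins"], "protein")
        references = read_fasta(paths["references"], "protein")
        truth_genes = pd.read_csv(paths["truth_genes"], sep="\t", keep_default_na=False)
        pair_truth = pd.read_csv(paths["truth_pairs"], sep="\t")
        reference_clans = {rid: rid.removeprefix("REF_") for rid in references.ids}
        pair_cds = cds.subset([i for i in cds.ids if i.startswith("PAIR")])
        family_cds = cds.subset([i for i in cds.ids if not i.startswith("PAIR")])
    else:
        family_cds, proteins, truth = sd.generate_transcriptome(
            seeds["simulate"],
            n_erf=cfg["n_erf"], n_dreb=cfg["n_dreb"], n_ap2=cfg["n_ap2"],
            n_rav=cfg["n_rav"], n_negative=cfg["n_negative"],
            n_incomplete=cfg["n_incomplete"],
            clan_mutation_rate=cfg["clan_mutation_rate"],
        )
        pair_cds, pair_truth = sd.generate_divergent_pairs(
            seeds["pairs"], n_pairs=cfg["n_pairs"], omega=cfg["pair_omega"],
            ds_target=cfg["pair_ds"], n_codons=cfg["pair_codons"],
        )
        cds = SequenceSet.merge(family_cds, pair_cds)
        truth_genes = truth.genes
        references = truth.references
        reference_clans = truth.reference_clans
        write_fasta(cds, paths["cds"])
        write_fasta(proteins, paths["proteins"])
        write_fasta(references, paths["references"])
        truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        pair_truth.to_csv(paths["truth_pairs"], sep="\t", index=False)
        cache.update("simulate", sim_digest)
    manifest.stages["simulate"] = {
        "params_hash": sim_digest,
        "cached": cached,
        "counts": {"genes": len(proteins), "pair_cds": len(pair_cds)},
        "outputs": [str(p) for p in sim_outputs],
    }

    # --- stage: identify -----------------------------------------------------
    assignments = fi.identify_family(proteins)
    rows = []
    for gene_id, _protein in proteins:
        a = assignments[gene_id]
        props = fi.compute_protein_properties(cds[gene_id])
        rows.append(
            {
                "gene_id": gene_id,
                "subfamily": a.subfamily,
                "n_AP2": a.n_ap2,
                "has_B3": a.has_b3,
                "res14": a.diagnostic[0] if a.diagnostic else "",
                "res19": a.diagnostic[1] if a.diagnostic else "",
                "ambiguous": a.ambiguous_flag,
                "orf_bp": props.orf_length,
                "aa": props.protein_length,
                "mw_da": round(props.molecular_weight, 2),
                "pi": round(props.isoelectric_point, 2),
            }
        )
    assign_frame = pd.DataFrame(rows)
    assign_frame.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    subfamily_counts = {
        k: int((assign_frame["subfamily"] == k).sum())
        for k in ("ERF", "DREB", "AP2", "RAV")
    }
    identified = int((assign_frame["subfamily"] != "excluded").sum())
    # subfamily counts must partition the identified set
    assert identified == sum(subfamily_counts.values())
    manifest.stages["identify"] = {
        "counts": {"identified": identified, **subfamily_counts,
                   "excluded": int((assign_frame["subfamily"] == "excluded").sum())},
        "outputs": [str(outdir / "assignments.tsv")],
    }

    # --- stage: tree & clans -------------------------------------------------
    family_ids = [g for g, a in assignments.items() if a.subfamily != "excluded"]
    if len(family_ids) >= 3:
        msa = ph.progressive_align(proteins.subset(family_ids))
        tree = ph.bootstrap_support(
            msa, n_replicates=cfg["bootstrap_replicates"], seed=seeds["tree"],
            model=cfg["distance_model"],
        )
        write_newick(tree, outdir / "tree.nwk")
        overrides = {
            g: assignments[g].subfamily
            for g in family_ids
            if assignments[g].subfamily in ("AP2", "RAV")
        }
        clans = ph.assign_clans(
            proteins.subset(family_ids), references, reference_clans, overrides
        )
        pd.DataFrame(
            [{"gene_id": c.gene_id, "clan": c.clan, "margin": round(c.margin, 6)}
             for c in clans]
        ).to_csv(outdir / "clans.tsv", sep="\t", index=False)
        manifest.stages["tree"] = {
            "counts": {"leaves": len(family_ids), "clan_assignments": len(clans)},
            "outputs": [str(outdir / "tree.nwk"), str(outdir / "clans.tsv")],
        }
    else:
        manifest.stages["tree"] = {"skipped": "fewer than 3 identified genes"}

    # --- stage: homolog pairs & Ka/Ks ---------------------------------------
    pairs = sa.find_homolog_pairs(cds)
    kaks_rows = []
    for pair in pairs:
        try:
            res = sa.compute_kaks(cds[pair.gene_a], cds[pair.gene_b],
                                  pair.gene_a, pair.gene_b)
        except ValueError as exc:  # saturated or too few compared codons
            logger.info("kaks %s/%s: %s", pair.gene_a, pair.gene_b, exc)
            kaks_rows.append(
                {"pair": f"{pair.gene_a}/{pair.gene_b}", "Ka": "NA",
                 "Ks": "NA", "Ka/Ks": "NA", "class": "undefined"}
            )
            continue
        ratio = "NA" if res.ratio is None else f"{res.ratio:.6f}"
        kaks_rows.append(
            {
                "pair": f"{pair.gene_a}/{pair.gene_b}",
                "Ka": f"{res.ka:.6f}",
                "Ks": f"{res.ks:.6f}",
                "Ka/Ks": ratio,
                "class": res.selection_class,
            }
        )
    pd.DataFrame(
        kaks_rows, columns=["pair", "Ka", "Ks", "Ka/Ks", "class"]
    ).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
    manifest.stages["kaks"] = {
        "counts": {"pairs": len(pairs)},
        "outputs": [str(outdir / "kaks.tsv")],
    }

    # --- stage: expression / DEG / networks ----------------------------------
    if cfg["expression"]:
        groups = tuple(cfg["expression_groups"])
        fam_pool = sorted(family_ids)[: cfg["n_expression_genes"]]
        path_ids = [f"PATH{i + 1:03d}" for i in range(cfg["n_pathway_genes"])]
        # modules mix family and pathway genes so cross-category edges exist
        modules: list[list[str]] = []
        fam_cursor = path_cursor = 0
        half = max(1, cfg["module_size"] // 2)
        for _ in range(cfg["n_modules"]):
            members = (
                fam_pool[fam_cursor : fam_cursor + half]
                + path_ids[path_cursor : path_cursor + (cfg["module_size"] - half)]
            )
            fam_cursor += half
            path_cursor += cfg["module_size"] - half
            if len(members) == cfg["module_size"]:
                modules.append(members)
        de_pool = [g for g in fam_pool if not any(g in m for m in modules)]
        de_specs = {
            g: (groups[-1], cfg["de_fold"]) for g in de_pool[: cfg["n_de_genes"]]
        }
        matrix, expr_truth = sd.generate_expression(
            seeds["expression"],
            gene_ids=fam_pool + path_ids,
            groups=groups,
            n_replicates=cfg["n_replicates"],
            sigma=cfg["expr_sigma"],
            de_specs=de_specs,
            modules=modules,
            module_loading=cfg["module_loading"],
        )
        write_matrix_tsv(matrix, paths["fpkm"])
        expr_truth.modules.to_csv(paths["truth_modules"], sep="\t", index=False)
        expressed = ea.filter_expressed(matrix, cfg["min_fpkm"])
        deg_calls = []
        for other in groups[1:]:
            deg_calls.extend(
                ea.call_degs(matrix, groups[0], other,
                             cfg["fc_threshold"], cfg["p_threshold"])
            )
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "comparison": f"{c.comparison[0]}_vs_{c.comparison[1]}",
                    "fc": f"{c.fold_change:.4f}",
                    "p": f"{c.p_value:.4g}",
                    "direction": c.direction,
                }
                for c in deg_calls
            ],
            columns=["gene_id", "comparison", "fc", "p", "direction"],
        ).to_csv(outdir / "degs.tsv", sep="\t", index=False)
        annotations = {g: {PATHWAY_DOMAIN_ID} for g in path_ids}
        pathway_genes = ea.screen_pathway_genes(annotations, [PATHWAY_DOMAIN_ID])
        edges = ea.coexpression_network(
            matrix, fam_pool, pathway_genes,
            p_max=cfg["p_threshold"], top_k=cfg["top_k"],
        )
        write_edgelist(edges, outdir / "edges.tsv")
        manifest.stages["expression"] = {
            "counts": {
                "genes": len(matrix.row_ids),
                "expressed": len(expressed),
                "degs": len(deg_calls),
                "edges": len(edges),
            },
            "outputs": [str(paths["fpkm"]), str(outdir / "degs.tsv"),
                        str(outdir / "edges.tsv")],
        }
    else:
        manifest.stages["expression"] = {"skipped": "expression block disabled"}

    # --- stage: qPCR ---------------------------------------------------------
    if cfg["qpcr"]:
        q_genes = tuple(sorted(family_ids)[: cfg["qpcr_genes"]])
        treatments = tuple(cfg["qpcr_treatments"])
        fold_profiles = {
            (g, t): {12: cfg["qpcr_fold"], 24: cfg["qpcr_fold"] / 2.0}
            for gi, g in enumerate(q_genes)
            for t in treatments
            if gi % 2 == 0  # half the genes respond, half are flat
        }
        ct = sd.generate_ct_tables(
            seeds["ct"], genes=q_genes, treatments=treatments,
            fold_profiles=fold_profiles,
        )
        ct.to_csv(paths["ct"], sep="\t", index=False)
        rel = qa.relative_expression(ct)
        rel.summary.to_csv(outdir / "rq.tsv", sep="\t", index=False)
        letter_rows = []
        for (gene, treatment), block in rel.replicates.groupby(
            ["gene_id", "treatment"]
        ):
            groups_rq = {
                str(tp): tp_block["rq"].to_numpy()
                for tp, tp_block in block.groupby("timepoint")
            }
            duncan = qa.anova_duncan(groups_rq)
            for _, row in duncan.table.iterrows():
                letter_rows.append(
                    {
                        "gene_id": gene,
                        "treatment": treatment,
                        "timepoint": row["group"],
                        "mean_rq": round(row["mean"], 4),
                        "letters": row["letters"],
                        "anova_p": f"{duncan.anova_p:.4g}",
                    }
                )
        pd.DataFrame(letter_rows).to_csv(outdir / "letters.tsv", sep="\t", index=False)
        q_edges = []
        for treatment in treatments:
            block = rel.summary[rel.summary["treatment"] == treatment]
            profiles = block.pivot(
                index="gene_id", columns="timepoint", values="mean_rq"
            )
            q_edges.extend(qa.qpcr_network(profiles))
        write_edgelist(q_edges, outdir / "qpcr_edges.tsv")
        manifest.stages["qpcr"] = {
            "counts": {"genes": len(q_genes), "edges": len(q_edges)},
            "outputs": [str(paths["ct"]), str(outdir / "rq.tsv"),
                        str(outdir / "letters.tsv"),
                        str(outdir / "qpcr_edges.tsv")],
        }
    else:
        manifest.stages["qpcr"] = {"skipped": "qPCR block disabled"}

    (outdir / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline complete: manifest hash %s", manifest.manifest_hash)
    return manifest
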