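"""End-to-end orchestration: diversity -> differentiation -> colonies ->
family calls -> bottleneck battery -> haplotype network -> IBD.

The run configuration is a flat TOML file; every stochastic stage takes an
explicit seed recorded in the output manifest, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from termipop import io as tio
from termipop import __version__
from termipop.bottleneck import heterozygosity_excess_battery
from termipop.delineation import merge_colonies, pairwise_colony_matrix
from termipop.diversity import (
    allele_counts,
    allelic_richness,
    gene_diversity,
    haplotype_diversity,
    nucleotide_diversity,
    summarize_diversity,
)
from termipop.families import classify_family
from termipop.ibd import ibd_within_site
from termipop.network import build_network

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genepop: str
    out_dir: str
    fasta: Optional[str] = None
    counts_csv: Optional[str] = None
    sites_csv: Optional[str] = None
    alpha: float = 0.05
    n_perm: int = 10_000
    n_iter: int = 10_000
    confidence: float = 0.95
    seed: int = 0
    do_diversity: bool = True
    do_difftest: bool = True
    do_colonies: bool = True
    do_classify: bool = True
    do_bottleneck: bool = True
    do_network: bool = True
    do_ibd: bool = True

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _diversity_frame(table, stat_frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format per-locus diversity table with mean/SD rows appended."""
    blocks = []
    for name, frame in stat_frames.items():
        summ = summarize_diversity(frame)
        block = summ.to_frame()
        block.insert(0, "statistic", name)
        block.insert(1, "locus", block.index)
        blocks.append(block.reset_index(drop=True))
    return pd.concat(blocks, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns the manifest dictionary.

    A failing stage aborts with its name in the exception; outputs written
    by earlier stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "termipop_version": __version__,
        "config": asdict(config),
        "outputs": {},
    }
    table = tio.read_genepop(config.genepop)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(2**31))
        for name in ("difftest", "colonies", "bottleneck", "ibd")
    }
    manifest["stage_seeds"] = stage_seeds

    def stage(name, enabled, fn):
        if not enabled:
            logger.info("stage %s disabled", name)
            return
        logger.info("stage %s ...", name)
        try:
            fn()
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e

    def _diversity():
        frames = {
            "Na": allele_counts(table),
            "Rs": allelic_richness(table),
            "Hs": gene_diversity(table),
        }
        path = out / "diversity.csv"
        _diversity_frame(table, frames).to_csv(path, index=False)
        manifest["outputs"]["diversity"] = str(path)
        if config.fasta:
            aln = tio.read_fasta_alignment(config.fasta, config.counts_csv)
            mt = pd.DataFrame(
                {
                    "Hd": [haplotype_diversity(aln)],
                    "Nd": [nucleotide_diversity(aln)],
                    "n_haplotypes": [len(aln.labels)],
                    "n_samples": [aln.n_samples],
                }
            )
            mt_path = out / "mtdna_diversity.csv"
            mt.to_csv(mt_path, index=False)
            manifest["outputs"]["mtdna_diversity"] = str(mt_path)

    pmatrix_holder: dict = {}

    def _difftest():
        m = pairwise_colony_matrix(
            table, n_perm=config.n_perm, seed=stage_seeds["difftest"]
        )
        pmatrix_holder["m"] = m
        path = out / "pairwise_p.csv"
        m.to_csv(path)
        manifest["outputs"]["pairwise_p"] = str(path)

    partition_holder: dict = {}

    def _colonies():
        m = pmatrix_holder.get("m")
        if m is None:
            m = pairwise_colony_matrix(
                table, n_perm=config.n_perm, seed=stage_seeds["colonies"]
            )
        part = merge_colonies(m, alpha=config.alpha)
        partition_holder["p"] = part
        rows = [
            {"group": g, "colony": cid}
            for cid, members in part.colonies.items()
            for g in members
        ]
        path = out / "colonies.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest["outputs"]["colonies"] = str(path)
        manifest["adjusted_alpha"] = part.adjusted_alpha

    def _classify():
        part = partition_holder.get("p")
        if part is not None:
            units = {
                cid: [r for g in members for r in table.members(g)]
                for cid, members in part.colonies.items()
            }
        else:
            units = {g: table.members(g) for g in table.groups}
        rows = []
        for cid, rws in units.items():
            rep = classify_family(table, rws, colony_id=cid, alpha=config.alpha)
            for ev in rep.evidence:
                rows.append(
                    {
                        "colony": cid,
                        "call": rep.call,
                        "mixed_not_excluded": rep.mixed_not_excluded,
                        "mendelian_G": rep.mendelian_g,
                        "mendelian_df": rep.mendelian_df,
                        "mendelian_p": rep.mendelian_p,
                        "locus": ev.locus,
                        "n_alleles": ev.n_alleles,
                        "n_genotype_classes": ev.n_genotype_classes,
                        "n_homozygote_classes": ev.n_homozygote_classes,
                        "single_pair_compatible": ev.single_pair_compatible,
                    }
                )
        path = out / "family_calls.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest["outputs"]["family_calls"] = str(path)

    def _bottleneck():
        rows = []
        for group in table.groups:
            rep = heterozygosity_excess_battery(
                table, group, n_iter=config.n_iter, seed=stage_seeds["bottleneck"]
            )
            for model, bat in rep.batteries.items():
                rows.append(
                    {
                        "group": group,
                        "model": model,
                        "sign_p": bat.sign_p,
                        "wilcoxon_one_tailed_p": bat.wilcoxon_one_tailed_p,
                        "wilcoxon_two_tailed_p": bat.wilcoxon_two_tailed_p,
                        "mode_shift": rep.mode_shift,
                        "n_loci": rep.n_loci_used,
                    }
                )
        path = out / "bottleneck.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest["outputs"]["bottleneck"] = str(path)

    def _network():
        if not config.fasta:
            logger.info("no FASTA supplied: network stage skipped")
            return
        aln = tio.read_fasta_alignment(config.fasta, config.counts_csv)
        net = build_network(aln, confidence=config.confidence)
        csv_path = out / "network_edges.csv"
        gml_path = out / "network.gml"
        net.write_edge_csv(csv_path)
        net.write_gml(gml_path)
        manifest["outputs"]["network_edges"] = str(csv_path)
        manifest["outputs"]["network_gml"] = str(gml_path)
        manifest["connection_limit"] = net.limit

    def _ibd():
        if not config.sites_csv:
            logger.info("no site table supplied: IBD stage skipped")
            return
        sites = tio.read_site_table(config.sites_csv)
        res = ibd_within_site(
            table, sites, n_perm=config.n_perm, seed=stage_seeds["ibd"]
        )
        path = out / "ibd.csv"
        pd.DataFrame(
            [
                {
                    "n_locations": res.n_locations,
                    "mantel_r": res.r,
                    "r2": res.r2,
                    "p": res.p,
                    "slope": res.slope,
                }
            ]
        ).to_csv(path, index=False)
        manifest["outputs"]["ibd"] = str(path)

    stage("diversity", config.do_diversity, _diversity)
    stage("difftest", config.do_difftest, _difftest)
    stage("colonies", config.do_colonies, _colonies)
    stage("classify", config.do_classify, _classify)
    stage("bottleneck", config.do_bottleneck, _bottleneck)
    stage("network", config.do_network, _network)
    stage("ibd", config.do_ibd, _ibd)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
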