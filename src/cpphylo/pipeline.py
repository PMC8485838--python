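"""Config-driven orchestration of the full analysis as one reproducible run.

Stages: ingest (FASTA + metadata, complete-column filtering) ->
haplotypes/network -> diversity -> structure (AMOVA, pairwise F_ST,
G_ST/N_ST, Mantel) -> demography (neutrality tests, mismatch) -> optional
desk-scale ABC.  Every stochastic stage derives its seed from the single
configured master seed; the run directory carries a manifest (package
version, seeds, input checksums) plus TSV reports shaped like the
familiar survey tables and machine-readable JSON twins.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import abc_inference as abc
from .alignment import (
    check_metadata_coverage,
    filter_complete_columns,
    read_alignment,
    read_metadata,
    write_alignment,
)
from .demography import fit_sudden_expansion, mismatch_observed, neutrality_tests
from .haplotypes import collapse_haplotypes, hamming_matrix, median_joining_network
from .popgen import (
    amova,
    great_circle_km,
    gst_nst,
    haplotype_diversity,
    mantel_test,
    nucleotide_diversity,
    pairwise_fst,
    tamura_nei_distance,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Round-trippable configuration for :func:`run_pipeline`."""

    fasta: str
    metadata: str
    out_dir: str
    seed: int = 0
    n_perm: int = 1000
    n_perm_gst: int = 10_000
    n_sim_neutrality: int = 1000
    n_boot_mismatch: int = 200
    mismatch_min_n: int = 8
    abc_n_sims: int = 2000
    abc_n_pods: int = 0
    abc_tolerance: float = 0.01
    min_pop_size: int = 1  # populations below this are dropped from AMOVA
    stages: dict[str, bool] = field(default_factory=lambda: {
        "network": True, "diversity": True, "structure": True,
        "demography": True, "abc": False,
    })

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["structure", "demography", "abc", "mantel"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage error is re-raised as ``RuntimeError`` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stage = "ingest"
    try:
        aln = read_alignment(config.fasta)
        meta = read_metadata(config.metadata)
        orphans = check_metadata_coverage(aln, meta)
        if orphans:
            logger.warning("metadata rows without alignment samples: %s", orphans)
        filtered, classes = filter_complete_columns(aln)
        write_alignment(filtered, out / "filtered.fasta")
        classes.write_tsv(out / "site_classes.tsv")
        meta_by_id = {m.sample_id: m for m in meta}
        lineage_of = {m.sample_id: m.lineage for m in meta}
        pop_of = {m.sample_id: m.population for m in meta}

        table = collapse_haplotypes(filtered, meta_by_id)
        table.write_tsv(out / "haplotypes.tsv")
        table.population_summary().to_csv(out / "haplotypes_by_population.tsv",
                                          sep="\t", index=False)

        if config.stages.get("network", True):
            stage = "network"
            net = median_joining_network(table)
            net.write_graphml(out / "network.graphml")
            net.write_nexus(out / "network.nex")

        if config.stages.get("diversity", True):
            stage = "diversity"
            rows = []
            groups = {"population": pop_of, "lineage": lineage_of}
            for level, mapping in groups.items():
                for value in dict.fromkeys(mapping[s] for s in filtered.sample_ids):
                    ids = [s for s in filtered.sample_ids if mapping[s] == value]
                    if len(ids) < 2:
                        rows.append((level, value, len(ids), 1, np.nan, np.nan, np.nan))
                        continue
                    seqs = [filtered.sequences[filtered.sample_ids.index(s)] for s in ids]
                    hap_counts = pd.Series(seqs).value_counts().to_numpy()
                    hd = haplotype_diversity(hap_counts)
                    pi = nucleotide_diversity(seqs)
                    rows.append((
                        level, value, len(ids), len(hap_counts),
                        round(hd.hd, 2), round(hd.hd_sd, 2), round(pi.pi, 5),
                    ))
            div = pd.DataFrame(
                rows, columns=["level", "unit", "n", "n_haplotypes", "Hd", "Hd_sd", "pi"]
            )
            div.to_csv(out / "diversity.tsv", sep="\t", index=False)
            div.to_json(out / "diversity.json", orient="records", indent=2)

        if config.stages.get("structure", True):
            stage = "structure"
            pops_series = pd.Series([pop_of[s] for s in filtered.sample_ids])
            keep_pops = pops_series.value_counts()
            keep_pops = keep_pops[keep_pops >= config.min_pop_size].index
            keep = pops_series.isin(keep_pops).to_numpy()
            ids = [s for s, k in zip(filtered.sample_ids, keep) if k]
            sub = filtered.subset(ids)
            dist = tamura_nei_distance(sub).to_numpy()
            pops = [pop_of[s] for s in ids]
            lineages = [lineage_of[s] for s in ids]
            rng_seed = seeds["structure"]
            two_group = {p: ("south" if lineage_of_pop == "south" else "north+central")
                         for p, lineage_of_pop in
                         {pop_of[s]: lineage_of[s] for s in ids}.items()}
            three_group = {pop_of[s]: lineage_of[s] for s in ids}
            results = {}
            results["no_groups"] = amova(dist, pops, n_perm=config.n_perm,
                                         seed=rng_seed, grouping_name="no_groups")
            results["two_lineages"] = amova(dist, pops, two_group, config.n_perm,
                                            rng_seed + 1, grouping_name="two_lineages")
            results["three_lineages"] = amova(dist, pops, three_group, config.n_perm,
                                              rng_seed + 2, grouping_name="three_lineages")
            amova_frames = []
            amova_json = {}
            for name, res in results.items():
                t = res.table.copy()
                t.insert(0, "grouping", name)
                amova_frames.append(t)
                amova_json[name] = {
                    "fixation_indices": res.fixation_indices,
                    "p_values": res.p_values,
                }
            pd.concat(amova_frames).to_csv(out / "amova.tsv", sep="\t", index=False)
            fst, fst_p = pairwise_fst(dist, lineages, config.n_perm, rng_seed + 3)
            fst.to_csv(out / "pairwise_fst.tsv", sep="\t")
            fst_p.to_csv(out / "pairwise_fst_p.tsv", sep="\t")
            hap_d = hamming_matrix(table.sequences)
            diff = gst_nst(table.counts, hap_d, config.n_perm_gst, rng_seed + 4)
            amova_json["gst_nst"] = {
                "G_ST": diff.g_st, "N_ST": diff.n_st, "p_NST_gt_GST": diff.p_nst_gt_gst,
            }
            # Mantel IBD on per-population G_ST-style distances vs km, when
            # coordinates are available for >= 3 populations with n >= 2
            coords = {}
            for m in meta:
                if m.latitude is not None and m.longitude is not None:
                    coords.setdefault(m.population, []).append((m.latitude, m.longitude))
            pop_n = pd.Series(pops).value_counts()
            usable = [p for p in pop_n[pop_n >= 2].index if p in coords]
            if len(usable) >= 3:
                gmat = np.zeros((len(usable), len(usable)))
                for i, a in enumerate(usable):
                    for j in range(i + 1, len(usable)):
                        b = usable[j]
                        pair = table.counts[[a, b]]
                        pair = pair[pair.sum(axis=1) > 0]
                        sub_d = hap_d[np.ix_(
                            [table.labels.index(h) for h in pair.index],
                            [table.labels.index(h) for h in pair.index])]
                        try:
                            coeff = gst_nst(pair, sub_d, n_perm=0)
                            gmat[i, j] = gmat[j, i] = coeff.g_st
                        except ValueError:
                            gmat[i, j] = gmat[j, i] = 0.0
                lat = np.array([np.mean([c[0] for c in coords[p]]) for p in usable])
                lon = np.array([np.mean([c[1] for c in coords[p]]) for p in usable])
                geo = great_circle_km(lat, lon)
                r, p = mantel_test(gmat, geo, config.n_perm, seeds["mantel"])
                amova_json["mantel_ibd"] = {"r": r, "p": p, "n_populations": len(usable)}
            (out / "structure.json").write_text(json.dumps(amova_json, indent=2))

        if config.stages.get("demography", True):
            stage = "demography"
            rows = []
            mismatch_rows = []
            for lineage in dict.fromkeys(lineage_of[s] for s in filtered.sample_ids):
                ids = [s for s in filtered.sample_ids if lineage_of[s] == lineage]
                seqs = [filtered.sequences[filtered.sample_ids.index(s)] for s in ids]
                n = len(ids)
                record: dict[str, object] = {"lineage": lineage, "N": n}
                if n >= 4:
                    try:
                        res = neutrality_tests(seqs, config.n_sim_neutrality,
                                               seeds["demography"])
                        record.update({
                            "N_H": res.n_haplotypes, "S": res.S,
                            "pi": round(nucleotide_diversity(seqs).pi, 5),
                            "Hd": round(haplotype_diversity(
                                pd.Series(seqs).value_counts().to_numpy()).hd, 3),
                            "D_T": res.D, "p_D": res.p_D,
                            "Fs": res.Fs, "p_Fs": res.p_Fs,
                            "R2": res.R2, "p_R2": res.p_R2,
                        })
                    except ValueError as exc:
                        record["note"] = str(exc)
                else:
                    record["note"] = "lineage too small for neutrality tests"
                obs = mismatch_observed(seqs) if n >= 2 else None
                if obs is not None:
                    for k, f in enumerate(obs):
                        mismatch_rows.append((lineage, k, f))
                if obs is not None and n >= config.mismatch_min_n:
                    try:
                        fit = fit_sudden_expansion(
                            obs, n, config.n_boot_mismatch,
                            seeds["demography"] + 1, config.mismatch_min_n,
                        )
                        record.update({
                            "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
                            "SSD": fit.ssd, "p_SSD": fit.p_ssd,
                            "Hri": fit.hri, "p_Hri": fit.p_hri,
                        })
                    except (ValueError, RuntimeError) as exc:
                        record["mismatch_note"] = str(exc)
                rows.append(record)
            demo = pd.DataFrame(rows)
            demo.to_csv(out / "demography.tsv", sep="\t", index=False)
            demo.to_json(out / "demography.json", orient="records", indent=2)
            pd.DataFrame(
                mismatch_rows, columns=["lineage", "differences", "frequency"]
            ).to_csv(out / "mismatch.tsv", sep="\t", index=False)

        if config.stages.get("abc", False):
            stage = "abc"
            lineages_all = [lineage_of[s] for s in filtered.sample_ids]
            observed = abc.summarize_alignment(filtered, lineages_all)
            sizes = pd.Series(lineages_all).value_counts().to_dict()
            ref = abc.build_reference_table(
                config.abc_n_sims, seeds["abc"],
                samples={g: sizes.get(g, 0) for g in abc.GROUPS},
                L=filtered.length,
                out_path=out / "reference_table.tsv",
            )
            choice = abc.model_choice(observed, ref, config.abc_tolerance,
                                      seed=seeds["abc"] + 1)
            result = {
                "posterior": choice.posterior.to_dict(),
                "ci_low": choice.ci_low.to_dict(),
                "ci_high": choice.ci_high.to_dict(),
                "rejection": choice.rejection.to_dict(),
                "chosen": choice.chosen,
            }
            est = abc.estimate_parameters(observed, ref, choice.chosen,
                                          config.abc_tolerance)
            result["parameters"] = est.summary.to_dict()
            if config.abc_n_pods > 0:
                rates = abc.pod_error_rates(
                    ref, config.abc_n_pods, seeds["abc"] + 2,
                    samples={g: sizes.get(g, 0) for g in abc.GROUPS},
                    L=filtered.length, tolerance=config.abc_tolerance,
                )
                result["error_rates"] = rates.to_dict()
            (out / "abc.json").write_text(json.dumps(result, indent=2, default=float))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "inputs": {
            "fasta": {"path": config.fasta, "sha256": _sha256(config.fasta)},
            "metadata": {"path": config.metadata, "sha256": _sha256(config.metadata)},
        },
        "config": dataclasses.asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
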