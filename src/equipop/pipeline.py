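"""Single-config orchestration of the full analysis graph.

``run_pipeline`` executes, in dependency order: simulation (or loading) of
inputs; the QC filter chain; LD pruning; per-sample/per-group diversity and
relatedness; pairwise F_ST with permutations; hierarchical AMOVA; PCA; the
three haplotype selection scans with peak calling and intersection; and the
window-based local-ancestry assignment.  Every stage logs its parameters and
seed, writes plain-text outputs (TSV/BED/JSON), and is recorded in a run
manifest; stages whose outputs already exist are skipped unless a dependency
re-ran, so deleting one stage's outputs regenerates only that stage and its
dependents.

Study-scale defaults are carried in :data:`DEFAULT_CONFIG` (maf 0.01,
genotyping-rate 0.20, HWE alpha 0.005, LD 50/5/0.5, IBD cap 0.25, 20000
permutations, 351-SNP scan windows, 99th percentile, posterior 0.99, G = 9);
the demo config scales simulation sizes down to desk scale without touching
those thresholds except the permutation count.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import differentiation as diff
from . import diversity as div
from . import genodata as gd
from . import structure_pca as spca
from . import sweepscan as sws
from . import synthpop as sp

log = logging.getLogger("equipop.pipeline")


class PipelineError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "out_dir": "equipop_run",
    "seed": 0,
    "simulate": asdict(sp.SimConfig()),
    "filters": {"maf": 0.01, "max_missing": 0.20, "hwe_alpha": 0.005},
    "ld": {"window": 50, "step": 5, "r2": 0.5},
    "ibd_max": 0.25,
    "fhat3_sd_mult": 2.0,
    "permutations": 20000,
    "pca_components": 4,
    "scan": {"window_snps": 351, "percentile": 99.0,
             "merge_gap_bp": 100_000, "max_span_bp": 5_000_000, "min_count": 2},
    "ancestry": {"window_snps": 50, "posterior": 0.99},
}

_STAGES = ["simulate", "qc", "ld", "diversity", "relatedness", "fst", "amova",
           "pca", "scan", "ancestry"]
_DEPS = {
    "simulate": [],
    "qc": ["simulate"],
    "ld": ["qc"],
    "diversity": ["qc"],
    "relatedness": ["qc"],
    "fst": ["qc"],
    "amova": ["qc"],
    "pca": ["ld"],
    "scan": ["simulate"],
    "ancestry": ["simulate"],
}


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (user or {}).items():
        if k not in cfg:
            raise PipelineError(f"unknown config key {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, dict):
            unknown = set(v) - set(cfg[k])
            if unknown:
                raise PipelineError(f"unknown config key {k}.{sorted(unknown)[0]}")
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def demo_config(out_dir="equipop_demo", seed: int = 0) -> dict:
    """Desk-scale demo: smaller simulation and permutation counts, same
    thresholds as the study-scale defaults."""
    return {
        "out_dir": str(out_dir),
        "seed": seed,
        "simulate": {"n_variants": 2500, "pop_n_haps": [24, 24, 24, 24],
                     "n_admixed": 4, "spacing_bp": 8000},
        "permutations": 99,
        "scan": {"window_snps": 51},
        "pca_components": 3,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, force: bool = False) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)

    master = np.random.default_rng(cfg["seed"])
    stage_seeds = {s: int(master.integers(2**31)) for s in _STAGES}

    manifest: dict = {"config": cfg, "stages": {}, "outputs": []}
    state: dict = {}
    reran: set[str] = set()
    try:
        for stage in _STAGES:
            outputs = _stage_outputs(stage, out)
            need = force or any(not p.exists() for p in outputs) or (reran & set(_DEPS[stage]))
            t0 = time.time()
            log.info("stage %s: %s (seed %d)", stage, "run" if need else "cached",
                     stage_seeds[stage])
            _run_stage(stage, cfg, out, stage_seeds[stage], state, write=bool(need))
            if need:
                reran.add(stage)
            rec = {
                "seed": stage_seeds[stage],
                "wall_s": round(time.time() - t0, 3),
                "outputs": [str(p) for p in outputs],
                "cached": not need,
            }
            rec.update(state.get(f"{stage}_counts", {}))
            manifest["stages"][stage] = rec
            manifest["outputs"].extend(str(p) for p in outputs)
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    manifest["input_hashes"] = {
        str(p): _sha256(Path(p)) for p in manifest["outputs"][:4] if Path(p).exists()
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return manifest


def _stage_outputs(stage: str, out: Path) -> list[Path]:
    table = {
        "simulate": ["refs.vcf", "admixed.vcf", "genotypes.ped", "genotypes.map",
                     "groups.tsv", "truth_tracts.bed", "truth.json"],
        "qc": ["filtered.ped", "filtered.map", "filter_report.tsv"],
        "ld": ["ld_keep.tsv"],
        "diversity": ["sample_diversity.tsv", "group_diversity.tsv", "group_comparisons.tsv"],
        "relatedness": ["pihat.tsv", "unrelated_samples.tsv"],
        "fst": ["fst.tsv"],
        "amova": ["amova.json"],
        "pca": ["pca_scores.tsv", "pca_scree.tsv"],
        "scan": ["scan_tracks.tsv", "scan_peaks.bed", "scan_candidates.tsv"],
        "ancestry": ["ancestry_segments.bed", "ancestry_fractions.tsv"],
    }
    return [out / name for name in table[stage]]


def _run_stage(stage: str, cfg: dict, out: Path, seed: int, state: dict,
               write: bool = True) -> None:
    # stages always recompute in memory (cheap at desk scale; dependents need
    # the in-memory state); `write` governs whether output files are touched
    if stage == "simulate":
        sim_cfg = sp.SimConfig(**{**cfg["simulate"],
                                  "pop_n_haps": tuple(cfg["simulate"]["pop_n_haps"]),
                                  "pop_names": tuple(cfg["simulate"]["pop_names"]),
                                  "pop_f": tuple(cfg["simulate"]["pop_f"]),
                                  "seed": seed})
        bundle = sp.simulate_cohort(sim_cfg)
        state["bundle"] = bundle
        refs = bundle["ref_haps"]
        all_ref = gd.HaplotypeMatrix(
            np.vstack([refs[p].alleles for p in sim_cfg.pop_names]),
            bundle["variants"].copy(),
            [s for p in sim_cfg.pop_names for s in refs[p].sample_ids],
        )
        state["all_ref"] = all_ref
        labels = [p for p in sim_cfg.pop_names for _ in refs[p].sample_ids]
        gm = all_ref.to_genotypes(pd.DataFrame({"id": all_ref.sample_ids, "breed": labels}))
        state["gm_raw"] = gm
        if write:
            gd.write_vcf_phased(all_ref, out / "refs.vcf")
            gd.write_vcf_phased(bundle["admixed"], out / "admixed.vcf")
            gd.write_ped_map(gm, out / "genotypes.ped", out / "genotypes.map")
            sp.write_group_tsv({p: list(refs[p].sample_ids) for p in sim_cfg.pop_names},
                               out / "groups.tsv")
            bundle["admix_truth"].tracts_to_bed(out / "truth_tracts.bed")
            bundle["sweep_truth"].to_json(out / "truth.json")
        state["simulate_counts"] = {"n_variants": gm.n_variants, "n_samples": gm.n_samples}

    elif stage == "qc":
        f = cfg["filters"]
        gm, report = gd.filter_variants(
            state["gm_raw"], maf_min=f["maf"], max_missing_rate=f["max_missing"],
            hwe_alpha=f["hwe_alpha"],
        )
        state["gm"] = gm
        if write:
            gd.write_ped_map(gm, out / "filtered.ped", out / "filtered.map")
            report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        state["qc_counts"] = {"n_variants": gm.n_variants}

    elif stage == "ld":
        keep = gd.ld_prune(state["gm"], cfg["ld"]["window"], cfg["ld"]["step"], cfg["ld"]["r2"])
        state["gm_pruned"] = state["gm"].take_variants(keep)
        if write:
            pd.DataFrame({"variant_id": state["gm"].variants["id"].iloc[keep]}).to_csv(
                out / "ld_keep.tsv", sep="\t", index=False)
        state["ld_counts"] = {"n_variants": len(keep)}

    elif stage == "diversity":
        gm = state["gm"]
        per = div.individual_heterozygosity(gm)
        per["fhat3"] = div.fhat3(gm).to_numpy()
        summary, comp = div.group_diversity(gm, gm.samples["breed"].to_numpy())
        if write:
            per.to_csv(out / "sample_diversity.tsv", sep="\t", index=False)
            summary.to_csv(out / "group_diversity.tsv", sep="\t", index=False)
            comp.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
        state["diversity_counts"] = {"n_groups": len(summary)}

    elif stage == "relatedness":
        rel = div.pairwise_ibd(state["gm"])
        retained = div.relatedness_filter(rel, cfg["ibd_max"])
        if write:
            rel.to_csv(out / "pihat.tsv", sep="\t")
            pd.DataFrame({"sample": retained}).to_csv(out / "unrelated_samples.tsv",
                                                      sep="\t", index=False)
        state["relatedness_counts"] = {"n_retained": len(retained)}

    elif stage == "fst":
        gm = state["gm"]
        breeds = gm.samples["breed"].to_numpy()
        pops = list(pd.unique(breeds))
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                mask = np.isin(breeds, [pops[i], pops[j]])
                sub = gm.take_samples(np.where(mask)[0])
                theta, p = diff.fst_permutation(
                    sub, breeds[mask], n_perm=min(cfg["permutations"], 199),
                    seed=int(rng.integers(2**31)))
                rows.append({"pop_a": pops[i], "pop_b": pops[j],
                             "fst": theta, "p_perm": p})
        if write:
            pd.DataFrame(rows).to_csv(out / "fst.tsv", sep="\t", index=False)
        state["fst_counts"] = {"n_pairs": len(rows)}

    elif stage == "amova":
        gm = state["gm"]
        breeds = gm.samples["breed"].to_numpy()
        pops = list(pd.unique(breeds))
        groups = {p: ("oriental" if i < 2 else "outgroup") for i, p in enumerate(pops)}
        hier = diff.Hierarchy(dict(zip(gm.samples["id"], breeds)), groups)
        res = diff.amova(gm, hier, n_perm=min(cfg["permutations"], 99), seed=seed)
        if write:
            with open(out / "amova.json", "w") as f:
                json.dump({"components": res.components, "percentages": res.percentages,
                           "phi": res.phi, "p_values": res.p_values,
                           "n_permutations": res.n_permutations}, f, indent=2)
        state["amova_counts"] = {}

    elif stage == "pca":
        res = spca.pca(state["gm_pruned"], k=cfg["pca_components"])
        scores = res.scores.copy()
        scores.insert(0, "sample", scores.index)
        scores["breed"] = state["gm_pruned"].samples["breed"].to_numpy()
        if write:
            scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
            pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(res.percent_variance))],
                          "percent_variance": res.percent_variance}).to_csv(
                out / "pca_scree.tsv", sep="\t", index=False)
        state["pca_counts"] = {"k": cfg["pca_components"]}

    elif stage == "scan":
        sc = cfg["scan"]
        swept = state["bundle"]["swept"]
        keep = sws.density_prune(swept.positions)
        swept = swept.take_variants(keep)
        tracks = [
            sws.h_scan(swept),
            sws.h12_windows(swept, sc["window_snps"]),
            sws.tajimas_d_windows(swept, sc["window_snps"]),
        ]
        tracks = [sws.scale_track(t) for t in tracks]
        for t in tracks:
            t.group = "swept"
        peaks = [sws.call_peaks(t, sc["percentile"], sc["max_span_bp"], sc["merge_gap_bp"])
                 for t in tracks]
        cand = sws.intersect_peaks(peaks, min_count=sc["min_count"])
        if write:
            pd.concat([t.to_frame() for t in tracks]).to_csv(
                out / "scan_tracks.tsv", sep="\t", index=False)
            pd.concat([p.to_bed_frame() for p in peaks]).to_csv(
                out / "scan_peaks.bed", sep="\t", index=False, header=False)
            cand.to_csv(out / "scan_candidates.tsv", sep="\t", index=False)
        state["scan_counts"] = {"n_peaksets": len(peaks), "n_candidates": len(cand)}

    elif stage == "ancestry":
        a = cfg["ancestry"]
        bundle = state["bundle"]
        ref = anc.reference_freqs(bundle["ref_haps"])
        admixed = bundle["admixed"]
        seg_frames, fracs = [], {}
        for i, sid in enumerate(admixed.sample_ids):
            s1, s2 = anc.assign_sample(admixed, i, ref, a["window_snps"], a["posterior"])
            frac = anc.ancestry_fractions([s1, s2])
            fracs[sid] = frac
            for s in (s1, s2):
                s.insert(0, "sample", sid)
                seg_frames.append(s)
        segs = pd.concat(seg_frames)
        segs["start"] = segs["start"] - 1  # BED half-open
        if write:
            segs[["chrom", "start", "end", "label", "posterior", "sample", "haplotype"]].to_csv(
                out / "ancestry_segments.bed", sep="\t", index=False, header=False)
            pd.DataFrame(fracs).T.fillna(0.0).rename_axis("sample").to_csv(
                out / "ancestry_fractions.tsv", sep="\t")
        state["ancestry_counts"] = {"n_samples": len(fracs)}


def run_demo(out_dir="equipop_demo", seed: int = 0) -> dict:
    """Run the full pipeline on the desk-scale synthetic fixture."""
    return run_pipeline(demo_config(out_dir, seed))
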