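"""End-to-end orchestration driven by a single YAML config.

All randomness flows from one root seed through named substreams per stage;
identical config + seed produces byte-identical outputs.  Each stage error
aborts the run with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import moderated_group_test
from .filtering import filter_probes
from .io import (
    write_beta_matrix,
    write_clock,
    write_manifest,
    write_regions_bed,
    write_sample_sheet,
    write_table,
    write_variants,
)
from .landscape import noncpg_analysis, region_shift, shift_fractions, substructure_shift
from .meth_age import age_gap, predict_age
from .subtyping import (
    aggregate_gene_beta,
    aggregate_region_beta,
    call_subclasses,
    delta_vs_healthy,
    pca_embed,
    select_hypermethylated_genes,
)
from .synthetic import (
    CohortConfig,
    VariantConfig,
    generate_clock,
    generate_cohort,
    generate_manifest,
    generate_references,
    generate_variants,
)
from .variant_filter import filter_variants

log = logging.getLogger("methylscape")

CONTRASTS = (("healthy", "AK"), ("healthy", "cSCC"), ("AK", "cSCC"))


class StageError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "synthetic" not in cfg:
        raise ValueError("config must contain a 'synthetic' block")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _cohort_config(cfg: dict) -> CohortConfig:
    synth = dict(cfg.get("synthetic", {}))
    synth.pop("n_clock_probes", None)
    synth.pop("n_variants", None)
    synth.setdefault("seed", cfg.get("seed", 0))
    return CohortConfig(**synth)


def synthesize(cfg: dict, outdir: Path) -> dict:
    """Generate and write the full synthetic input bundle."""
    outdir.mkdir(parents=True, exist_ok=True)
    ccfg = _cohort_config(cfg)
    bundle = generate_manifest(ccfg)
    clock = generate_clock(
        bundle, cfg.get("synthetic", {}).get("n_clock_probes", 50), seed=ccfg.seed
    )
    cohort = generate_cohort(bundle, ccfg, clock=clock)
    references = generate_references(bundle, ccfg)
    write_manifest(bundle.manifest, outdir / "manifest.tsv")
    write_beta_matrix(cohort.beta, outdir / "beta.tsv")
    write_sample_sheet(cohort.samples, outdir / "samplesheet.tsv")
    write_beta_matrix(references, outdir / "references.tsv")
    write_clock(clock, outdir / "clock.tsv")
    for name, rs in bundle.region_sets.items():
        write_regions_bed(rs, outdir / f"regions_{name}.bed")
    n_variants = cfg.get("synthetic", {}).get("n_variants", 0)
    variants = None
    if n_variants:
        variants = generate_variants(n_variants, VariantConfig(), seed=ccfg.seed)
        write_variants(variants, outdir / "variants.tsv")
    return {
        "bundle": bundle,
        "clock": clock,
        "cohort": cohort,
        "references": references,
        "variants": variants,
    }


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.monotonic()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.monotonic() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config, output_dir=None) -> dict:
    """Execute synth -> filter -> differential -> landscape -> age ->
    subtyping -> variant filter and write the report bundle.

    ``config`` is a YAML path or an already-loaded dict.  Returns a dict of
    in-memory stage results; files land under ``output_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(output_dir or config.get("output_dir", "methylscape_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    alpha = float(config.get("alpha", 0.05))
    results: dict = {}

    synth = _stage("synthesize")(synthesize)(config, outdir / "inputs")
    bundle, cohort = synth["bundle"], synth["cohort"]
    clock, references = synth["clock"], synth["references"]
    manifest = bundle.manifest
    samples = cohort.samples
    results["synth"] = synth

    @_stage("filter")
    def do_filter():
        beta, report = filter_probes(cohort.beta, manifest)
        with open(outdir / "filter_report.json", "w") as fh:
            json.dump(
                {"n_input": report.n_input, "n_retained": report.n_retained,
                 "removed": report.counts()},
                fh, indent=2,
            )
        return beta, report

    beta, filter_report = do_filter()
    results["filter"] = filter_report

    @_stage("differential")
    def do_diff():
        out = {}
        for a, b in CONTRASTS:
            res = moderated_group_test(beta, samples, (a, b), alpha=alpha)
            write_table(res.table, outdir / f"diff_{a}_vs_{b}.tsv")
            out[(a, b)] = res
        return out

    diffs = do_diff()
    results["differential"] = diffs

    @_stage("landscape")
    def do_landscape():
        out = {}
        for grp in ("AK", "cSCC"):
            shift = substructure_shift(beta, manifest, samples, "healthy", grp)
            write_table(shift.summary, outdir / f"substructure_healthy_vs_{grp}.tsv")
            fractions = shift_fractions(diffs[("healthy", grp)], manifest)
            write_table(fractions, outdir / f"fractions_healthy_vs_{grp}.tsv")
            lad = region_shift(
                beta, manifest, bundle.region_sets["LAD"], samples, "healthy", grp
            )
            out[grp] = {"shift": shift, "fractions": fractions, "lad": lad}
        ncpg = {
            grp: noncpg_analysis(beta, manifest, samples, "healthy", grp, alpha)
            for grp in ("AK", "cSCC")
        }
        summary = {
            grp: {
                "lad_mean_delta": out[grp]["lad"].mean_delta,
                "lad_p": out[grp]["lad"].p_value,
                "n_significant_ch": len(ncpg[grp].significant_probes),
            }
            for grp in ("AK", "cSCC")
        }
        with open(outdir / "landscape_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        out["noncpg"] = ncpg
        return out

    results["landscape"] = do_landscape()

    @_stage("age")
    def do_age():
        pred = predict_age(beta, clock)
        gaps = age_gap(pred, samples)
        write_table(gaps.per_sample, outdir / "age.tsv")
        write_table(gaps.per_group.to_frame(), outdir / "age_groups.tsv")
        return gaps

    results["age"] = do_age()

    @_stage("subtyping")
    def do_subtype():
        modes = config.get("subtyping", {}).get("modes", ["keratin", "enhancer"])
        floor = config.get("subtyping", {}).get("silhouette_floor", 0.15)
        out = {}
        for mode in modes:
            if mode == "keratin":
                features, _ = aggregate_gene_beta(beta, manifest, bundle.keratin_genes)
                refs, _ = aggregate_gene_beta(references, manifest, bundle.keratin_genes)
            elif mode == "enhancer":
                esc, _ = aggregate_region_beta(
                    beta, manifest, bundle.region_sets["ESC_enhancer"]
                )
                kc, _ = aggregate_region_beta(
                    beta, manifest, bundle.region_sets["KC_enhancer"]
                )
                features = pd.concat(
                    [esc, kc.loc[kc.index.difference(esc.index)]]
                )
                refs = None
            else:
                raise ValueError(f"unknown subtyping mode {mode!r}")
            call = call_subclasses(
                features, samples, refs, method=mode, silhouette_floor=floor
            )
            write_table(call.calls, outdir / f"subtype_{mode}.tsv")
            pca = pca_embed(features)
            write_table(pca.coordinates, outdir / f"pca_{mode}.tsv")
            if call.dendrogram is not None:
                (outdir / f"dendrogram_{mode}.nwk").write_text(
                    call.dendrogram.to_newick() + "\n"
                )
            out[mode] = call
        if {"keratin", "enhancer"} <= set(out) and not any(
            out[m].no_structure for m in ("keratin", "enhancer")
        ):
            k = out["keratin"].calls["subclass"]
            e = out["enhancer"].calls["subclass"]
            common = k.index.intersection(e.index)
            agreement = float((k.loc[common] == e.loc[common]).mean())
        else:
            agreement = None
        with open(outdir / "subtype_agreement.json", "w") as fh:
            json.dump(
                {
                    "agreement": agreement,
                    "no_structure": {m: out[m].no_structure for m in out},
                    "silhouette": {m: out[m].silhouette for m in out},
                },
                fh, indent=2,
            )
        gained = bundle.region_sets["EpSC_gained"]
        gained_matrix, _ = aggregate_region_beta(beta, manifest, gained)
        delta = delta_vs_healthy(gained_matrix, samples)
        write_table(delta, outdir / "delta_gained_vs_healthy.tsv")
        enh_call = out.get("enhancer") or out.get("keratin")
        if enh_call is not None and not enh_call.no_structure:
            genes = select_hypermethylated_genes(
                delta, gained.region_genes or {}, enh_call.calls
            )
        else:
            genes = []
        (outdir / "hypermethylated_genes.txt").write_text(
            "\n".join(genes) + ("\n" if genes else "")
        )
        out["agreement"] = agreement
        out["hypermethylated_genes"] = genes
        return out

    results["subtyping"] = do_subtype()

    if synth["variants"] is not None:
        @_stage("variant_filter")
        def do_variants():
            vcfg = config.get("variants", {})
            retained, report = filter_variants(
                synth["variants"],
                min_score=vcfg.get("min_score", 8),
                depth_bounds=tuple(vcfg["depth_bounds"])
                if "depth_bounds" in vcfg
                else None,
            )
            write_variants(retained, outdir / "variants_retained.tsv")
            with open(outdir / "variant_report.json", "w") as fh:
                json.dump(asdict(report), fh, indent=2)
            return retained, report

        results["variants"] = do_variants()
    else:
        log.info("variant stage skipped (no synthetic variants configured)")

    manifest_record = {
        "version": __version__,
        "seed": config.get("seed", 0),
        "config_hash": _config_hash(config),
        "config": config,
        "outputs": sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest_record, fh, indent=2, default=str)
    return results
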