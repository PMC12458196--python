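"""End-to-end pipeline orchestration, run manifest, and report rendering.

Stage order: simulate/load -> qc -> genotype -> remove-background -> demux
-> clones -> bias. Each stage writes plain-text outputs under the run
directory and records its parameters, row counts, and output-file SHA-256
digests in a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .ambient import remove_background
from .clonal import binarize_presence, cluster_clones, lineage_bias, select_top_variants
from .counts import (
    BarcodeRecord,
    StrandBaseCounts,
    read_barcode_summary,
    read_strand_counts,
)
from .demux import (
    assign_cells,
    estimate_contamination,
    identify_homoplasmic_variants,
    infer_donor_profiles,
)
from .errors import StageError
from .genotyping import (
    call_candidate_variants,
    compute_heteroplasmy,
    compute_variant_metrics,
    drop_artifact_variants,
    filter_high_confidence,
    substitution_spectrum,
)
from .qc import filter_cells, get_profile, per_cell_mtdna_depth
from .simulate import simulate_experiment, two_donor_mixing_config

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, params: Mapping[str, Any], counts: Mapping[str, int],
                  outputs: Mapping[str, Path], elapsed: float) -> None:
        if any(s["name"] == name for s in self.stages):
            raise StageError(name, "stage recorded twice")
        self.stages.append(
            {
                "name": name,
                "params": dict(params),
                "counts": {k: int(v) for k, v in counts.items()},
                "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in outputs.items()},
                "elapsed_s": round(elapsed, 3),
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "version": self.version, "stages": self.stages},
            indent=2,
            sort_keys=True,
        )

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def verify_digests(self) -> bool:
        for s in self.stages:
            for out in s["outputs"].values():
                if _sha256(Path(out["path"])) != out["sha256"]:
                    return False
        return True

    def stage(self, name: str) -> dict:
        for s in self.stages:
            if s["name"] == name:
                return s
        raise KeyError(name)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full pipeline from a config mapping or YAML path.

    Config keys: ``seed``, ``out_dir``, and per-stage sections
    ``simulate`` (preset parameters) or ``input`` (paths to counts dir,
    singlecell.csv, reference, cell-type TSV), ``qc`` (profile name),
    ``ambient``, ``demux`` (k), ``clones`` (top_n, threshold), ``bias``.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "cryoclone_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed)

    # -- stage 1: simulate or load ------------------------------------------
    t0 = time.time()
    celltype_map: dict[str, str] = {}
    try:
        if "input" in config:
            spec = config["input"]
            tensor = read_strand_counts(spec["counts_dir"])
            records = read_barcode_summary(spec["singlecell"], dialect=spec.get("dialect", "named"))
            reference = Path(spec["reference"]).read_text().strip() if "reference" in spec else None
            if "celltypes" in spec:
                for ln in Path(spec["celltypes"]).read_text().splitlines()[1:]:
                    bc, ct = ln.split("\t")[:2]
                    celltype_map[bc] = ct
            truth = None
            stage_name = "load"
            params = dict(spec)
        else:
            sim = dict(config.get("simulate", {}))
            sim.setdefault("seed", seed)
            cfg = two_donor_mixing_config(**sim)
            tensor, records, truth = simulate_experiment(cfg)
            reference = truth.reference
            celltype_map = {
                b: t.cell_type or "unknown" for b, t in truth.barcodes.items() if t.is_cell
            }
            stage_name = "simulate"
            params = sim
    except StageError:
        raise
    except Exception as exc:
        manifest.save(out / "manifest.json")
        raise StageError("simulate/load", str(exc)) from exc
    manifest.add_stage(
        stage_name, params,
        {"barcodes": len(tensor.barcodes), "total_counts": tensor.total_counts()},
        {}, time.time() - t0,
    )

    # -- stage 2: qc ---------------------------------------------------------
    t0 = time.time()
    try:
        qc_cfg = config.get("qc", {})
        profile = get_profile(qc_cfg.get("profile", "default"))
        depths = per_cell_mtdna_depth(tensor)
        candidates = [r for r in records if r.is_cell]
        kept, reasons = filter_cells(candidates, depths, profile)
        kept_cells = sorted(kept)
        kept_path = out / "kept_barcodes.tsv"
        kept_path.write_text("".join(f"{b}\n" for b in kept_cells))
        rej_path = out / "rejected_barcodes.tsv"
        with rej_path.open("w") as fh:
            fh.write("barcode\treasons\n")
            for b in sorted(reasons):
                fh.write(f"{b}\t{','.join(reasons[b])}\n")
    except Exception as exc:
        manifest.save(out / "manifest.json")
        raise StageError("qc", str(exc)) from exc
    manifest.add_stage(
        "qc", {"profile": profile.name},
        {"cells_in": len(candidates), "cells_out": len(kept_cells)},
        {"kept": kept_path, "rejected": rej_path}, time.time() - t0,
    )

    # -- stage 3: genotype ----------------------------------------------------
    t0 = time.time()
    try:
        if reference is None:
            raise ValueError("a reference sequence is required for variant calling")
        candidates_v = call_candidate_variants(tensor, reference, kept_cells)
        het = compute_heteroplasmy(tensor, candidates_v, kept_cells)
        metrics = compute_variant_metrics(het)
        hc = filter_high_confidence(metrics)
        hc = drop_artifact_variants(hc)
        metrics_path = out / "variant_metrics.tsv"
        _write_metrics(metrics, metrics_path, set(hc))
        spectrum_path = out / "substitution_spectrum.tsv"
        substitution_spectrum(candidates_v).to_csv(spectrum_path, sep="\t")
    except Exception as exc:
        manifest.save(out / "manifest.json")
        raise StageError("genotype", str(exc)) from exc
    manifest.add_stage(
        "genotype", {"cells_in": len(kept_cells)},
        {"cells_in": len(kept_cells), "variants_called": len(candidates_v),
         "variants_high_confidence": len(hc)},
        {"metrics": metrics_path, "spectrum": spectrum_path}, time.time() - t0,
    )

    # -- stage 4: remove-background ------------------------------------------
    t0 = time.time()
    try:
        amb_cfg = dict(config.get("ambient", {}))
        result, report = remove_background(
            tensor, records, kept_cells, variants=candidates_v, **amb_cfg
        )
        corrected = result.corrected
        amb_path = out / "ambient_report.json"
        amb_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        manifest.save(out / "manifest.json")
        raise StageError("remove-background", str(exc)) from exc
    manifest.add_stage(
        "remove-background", amb_cfg,
        {"cells_in": len(kept_cells), "empty_droplets": report.n_empty_droplets,
         "reads_removed": report.total_removed},
        {"report": amb_path}, time.time() - t0,
    )

    # -- stage 5: demux -------------------------------------------------------
    t0 = time.time()
    try:
        demux_cfg = config.get("demux", {})
        k = int(demux_cfg.get("k", 2))
        from .demux import SHALLOW_COVERAGE_BIMODAL_PARAMS

        het_pre = het
        het_post = compute_heteroplasmy(corrected, candidates_v, kept_cells)
        bimodal = {
            key: demux_cfg.get(key, default)
            for key, default in SHALLOW_COVERAGE_BIMODAL_PARAMS.items()
        }
        shared, discr = identify_homoplasmic_variants(het_post, **bimodal)
        contamination = {"pre_percent": None, "post_percent": None}
        assignments = []
        if k >= 2 and discr:
            profiles, _labels = infer_donor_profiles(het_post, discr, k)
            assignments = assign_cells(het_post, profiles, discr)
            _, post_pct, _ = estimate_contamination(het_post, assignments, profiles)
            pre_assign = assign_cells(het_pre, profiles, discr)
            _, pre_pct, _ = estimate_contamination(het_pre, pre_assign, profiles)
            contamination = {"pre_percent": pre_pct, "post_percent": post_pct}
        assign_path = out / "assignments.tsv"
        with assign_path.open("w") as fh:
            fh.write("barcode\tcall\tcontamination\n")
            for a in assignments:
                c = "" if a.contamination is None else f"{a.contamination:.6g}"
                fh.write(f"{a.cell}\t{a.call}\t{c}\n")
        contam_path = out / "contamination.json"
        contam_path.write_text(json.dumps(contamination, indent=2) + "\n")
    except Exception as exc:
        manifest.save(out / "manifest.json")
        raise StageError("demux", str(exc)) from exc
    manifest.add_stage(
        "demux", {"k": k},
        {"cells_in": len(kept_cells), "discriminating_variants": len(discr),
         "shared_homoplasmic": len(shared)},
        {"assignments": assign_path, "contamination": contam_path}, time.time() - t0,
    )

    # -- stage 6: clones ------------------------------------------------------
    t0 = time.time()
    try:
        clone_cfg = config.get("clones", {})
        top_n = int(clone_cfg.get("top_n", 50))
        threshold = float(clone_cfg.get("threshold", 0.20))
        germline = set(shared) | set(discr)
        somatic_metrics = [
            m for m in compute_variant_metrics(het_post) if m.variant not in germline
        ]
        clones_path = out / "clones.tsv"
        n_clones = 0
        n_retained = 0
        if somatic_metrics:
            top = select_top_variants(somatic_metrics, n=top_n)
            het_top = compute_heteroplasmy(corrected, top, kept_cells)
            presence = binarize_presence(het_top, threshold=threshold)
            if presence.retained_cells:
                assignment = cluster_clones(presence)
                n_clones = len(assignment.clone_sizes)
                n_retained = len(assignment.labels)
                with clones_path.open("w") as fh:
                    fh.write("barcode\tclone\n")
                    for b in sorted(assignment.labels):
                        fh.write(f"{b}\t{assignment.labels[b]}\n")
        if not clones_path.exists():
            clones_path.write_text("barcode\tclone\n")
    except Exception as exc:
        manifest.save(out / "manifest.json")
        raise StageError("clones", str(exc)) from exc
    manifest.add_stage(
        "clones", {"top_n": top_n, "threshold": threshold},
        {"cells_in": len(kept_cells), "cells_retained": n_retained, "clones": n_clones},
        {"clones": clones_path}, time.time() - t0,
    )

    # -- stage 7: bias --------------------------------------------------------
    t0 = time.time()
    try:
        bias_path = out / "bias.tsv"
        groups = {c: celltype_map.get(c, "unknown") for c in kept_cells}
        tested = 0
        if somatic_metrics and len(set(groups.values())) >= 2:
            test_vars = [m.variant for m in somatic_metrics]
            het_bias = compute_heteroplasmy(corrected, test_vars, kept_cells)
            table = lineage_bias(het_bias, groups)
            table.to_csv(bias_path, sep="\t")
            tested = len(table)
        else:
            bias_path.write_text("variant\tH\tp\tp_adj\n")
    except Exception as exc:
        manifest.save(out / "manifest.json")
        raise StageError("bias", str(exc)) from exc
    manifest.add_stage(
        "bias", {}, {"cells_in": len(kept_cells), "variants_tested": tested},
        {"bias": bias_path}, time.time() - t0,
    )

    manifest.save(out / "manifest.json")
    return manifest


def _write_metrics(metrics, path: Path, high_confidence: set) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "variant\tn_cells_conf_detected\tstrand_concordance\tmean_coverage\t"
            "log10_vmr\tpseudobulk_het_mean\tpseudobulk_het_aggregate\t"
            "n_cells_over_threshold\thigh_confidence\n"
        )
        for m in metrics:
            sc = "" if m.strand_concordance is None else f"{m.strand_concordance:.6g}"
            vmr = "" if m.log10_vmr is None else f"{m.log10_vmr:.6g}"
            fh.write(
                f"{m.variant.label}\t{m.n_cells_conf_detected}\t{sc}\t"
                f"{m.mean_coverage:.6g}\t{vmr}\t{m.pseudobulk_het_mean:.6g}\t"
                f"{m.pseudobulk_het_aggregate:.6g}\t{m.n_cells_over_threshold}\t"
                f"{int(m.variant in high_confidence)}\n"
            )


def render_report(manifest: RunManifest | str | Path, out_dir: str | Path,
                  plots: bool = False) -> Path:
    """Render a plain-text run report from a manifest; optional PNG plots."""
    if not isinstance(manifest, RunManifest):
        data = json.loads(Path(manifest).read_text())
        m = RunManifest(seed=data["seed"], version=data["version"])
        m.stages = data["stages"]
        manifest = m
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [
        "cryoclone run report",
        "====================",
        f"version: {manifest.version}   seed: {manifest.seed}",
        "",
    ]
    for s in manifest.stages:
        lines.append(f"[{s['name']}]  ({s['elapsed_s']} s)")
        for k, v in sorted(s["counts"].items()):
            lines.append(f"  {k}: {v}")
        for k, o in sorted(s["outputs"].items()):
            lines.append(f"  {k} -> {o['path']}")
        lines.append("")
    try:
        clones_file = Path(manifest.stage("clones")["outputs"]["clones"]["path"])
        body = clones_file.read_text().splitlines()[1:]
        if not body:
            lines.append("clones: none detected")
    except (KeyError, FileNotFoundError):
        lines.append("clones: section absent")
    try:
        contam_file = Path(manifest.stage("demux")["outputs"]["contamination"]["path"])
        contam = json.loads(contam_file.read_text())
        lines.append(
            f"contamination: pre={contam.get('pre_percent')}%  post={contam.get('post_percent')}%"
        )
    except (KeyError, FileNotFoundError):
        lines.append("contamination: section absent")
    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    if plots:
        _render_plots(manifest, out_dir)
    return report_path


def _render_plots(manifest: RunManifest, out_dir: Path) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    try:
        spec_file = Path(manifest.stage("genotype")["outputs"]["spectrum"]["path"])
        df = pd.read_csv(spec_file, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(df["class"], df["count"])
        ax.set_ylabel("count")
        ax.set_title("substitution spectrum")
        plt.xticks(rotation=45)
        fig.tight_layout()
        fig.savefig(out_dir / "spectrum.png", dpi=100)
        plt.close(fig)
    except (KeyError, FileNotFoundError):
        pass
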