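"""End-to-end pipeline: simulate -> count -> TE -> length profile -> group
tests -> trace quantification, with a reproducibility manifest.

Stages communicate only through documented text formats (TSV/CSV), so any
stage can be re-run standalone on the previous stage's outputs. All
randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .counting import (
    CountMatrix,
    Offsets,
    count_reads,
    read_alignments_tsv,
    write_alignments_tsv,
)
from .errors import ConfigurationError
from .genesets import geneset_percent_summary, length_corrected_test, load_genesets, mwu_geneset_test
from .lengths import binned_profile, correlate_attribute
from .normalize import te_analysis, write_te_table
from .simulate import (
    GroupDef,
    SimulationConfig,
    default_polysome_spec,
    simulate_experiment,
    simulate_reads,
    simulate_trace,
)
from .trace import PolysomeTrace, quantify_trace

__all__ = ["PipelineConfig", "run_all"]

_FLOAT_FMT = "%.8g"


class PipelineConfig:
    """Validated pipeline configuration loaded from a YAML mapping."""

    def __init__(self, raw: dict[str, Any], base_dir: Path = Path(".")):
        if not isinstance(raw, dict):
            raise ConfigurationError("pipeline config must be a mapping")
        self.raw = raw
        self.base_dir = base_dir
        self.seed = int(raw.get("seed", 0))
        self.outdir = Path(raw.get("outdir", "riboten_out"))
        if not self.outdir.is_absolute():
            self.outdir = base_dir / self.outdir
        self.simulate = dict(raw.get("simulate", {}))
        self.count = dict(raw.get("count", {}))
        self.te = dict(raw.get("te", {}))
        self.lengthprofile = dict(raw.get("lengthprofile", {}))
        self.groups = dict(raw.get("groups", {}))
        self.trace = dict(raw.get("trace", {}))
        # referenced input files must exist before any stage runs
        for section, key in (("groups", "sets"), ("trace", "input")):
            path = getattr(self, section).get(key)
            if path is not None and not (base_dir / path).exists():
                raise ConfigurationError(f"{section}.{key}: no such file {path!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw, base_dir=path.parent)

    def simulation_config(self) -> SimulationConfig:
        params = {k: v for k, v in self.simulate.items() if k != "contamination_frac"}
        groups = params.pop("group_defs", None)
        gdefs = tuple(
            GroupDef(
                name=g["name"],
                quantile_range=tuple(g["quantile_range"]) if "quantile_range" in g else None,
                gene_ids=tuple(g["gene_ids"]) if "gene_ids" in g else None,
                size=g.get("size"),
                extra_shift_log2=float(g.get("extra_shift_log2", 0.0)),
            )
            for g in (groups or [])
        )
        if "conditions" in params:
            params["conditions"] = tuple(params["conditions"])
        return SimulationConfig(seed=self.seed, group_defs=gdefs, **params)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _lib_filename(lib_id: str) -> str:
    return f"alignments_{lib_id.replace(':', '_')}.tsv"


def run_all(config: PipelineConfig, outdir: Optional[Path] = None) -> dict:
    """Execute every stage; returns (and writes) the run manifest.

    The manifest records the tool version, a config hash, per-stage output
    checksums and wall-clock seconds. Re-running with the same config and
    seed reproduces identical checksums.
    """
    outdir = Path(outdir) if outdir is not None else config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "riboten",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }

    def record(stage: str, t0: float, outputs: list[Path], caught: list) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        manifest["warnings"].extend(f"{stage}: {w.message}" for w in caught)

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    sim_cfg = config.simulation_config()
    contamination = float(config.simulate.get("contamination_frac", 0.0))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        annotation, truth, counts = simulate_experiment(sim_cfg)
        outputs = []
        ann_path = outdir / "annotation.tsv"
        annotation.to_tsv(ann_path)
        outputs.append(ann_path)
        truth_path = outdir / "truth.tsv"
        truth.to_tsv(truth_path)
        outputs.append(truth_path)
        offsets = Offsets(**config.count) if config.count else Offsets()
        for i, lib in enumerate(counts.counts.columns):
            reads = simulate_reads(
                annotation,
                counts.counts[lib],
                contamination_frac=contamination,
                read_length=sim_cfg.read_length,
                offsets=offsets,
                seed=config.seed * 1009 + i,
            )
            path = outdir / _lib_filename(lib)
            write_alignments_tsv(path, reads)
            outputs.append(path)
        if config.trace.get("input") is None:
            trace, _ = simulate_trace(default_polysome_spec(seed=config.seed))
            trace_path = outdir / "trace.csv"
            trace.to_csv(trace_path)
            outputs.append(trace_path)
        if config.groups.get("sets") is None and truth.groups:
            sets_path = outdir / "groups_truth.tsv"
            rows = [
                {"gene_id": g, "group": name}
                for name, members in truth.groups.items()
                for g in members
            ]
            pd.DataFrame(rows, columns=["gene_id", "group"]).to_csv(
                sets_path, sep="\t", index=False
            )
            outputs.append(sets_path)
    record("simulate", t0, outputs, caught)

    # --- count --------------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        columns, discard_rows = {}, []
        for lib in counts.counts.columns:
            series, discards = count_reads(
                read_alignments_tsv(outdir / _lib_filename(lib)), annotation, offsets
            )
            columns[lib] = series
            discard_rows.append({"library": lib, "counted": int(series.sum()), **discards})
        counted = CountMatrix(pd.DataFrame(columns))
        counts_path = outdir / "counts.tsv"
        counted.to_tsv(counts_path)
        discard_path = outdir / "discards.tsv"
        pd.DataFrame(discard_rows).fillna(0).convert_dtypes().to_csv(
            discard_path, sep="\t", index=False
        )
    record("count", t0, [counts_path, discard_path], caught)

    # --- te -----------------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        te_kwargs = dict(config.te)
        te_kwargs.setdefault("wt", sim_cfg.conditions[0])
        te_kwargs.setdefault("mut", sim_cfg.conditions[1])
        result = te_analysis(counted, **te_kwargs)
        te_path = outdir / "te.tsv"
        write_te_table(result, te_path)
    record("te", t0, [te_path], caught)
    table = result.table

    # --- lengthprofile ------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lengths = annotation.orf_lengths()
        profile = binned_profile(
            table["dte_percent"],
            lengths,
            bin_size=int(config.lengthprofile.get("bin_size", 100)),
            exclude_ids=config.lengthprofile.get("exclude", []),
        )
        profile_path = outdir / "profile.tsv"
        profile.to_csv(profile_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        corr = correlate_attribute(table["dte_log2"], lengths.loc[table.index])
        corr_path = outdir / "correlations.tsv"
        pd.DataFrame(
            [{"attribute": "orf_length", "method": corr.method, "r": corr.r, "p": corr.p, "n": corr.n}]
        ).to_csv(corr_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    record("lengthprofile", t0, [profile_path, corr_path], caught)

    # --- groups -------------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sets_file = config.groups.get("sets")
        sets_path = (
            config.base_dir / sets_file if sets_file else outdir / "groups_truth.tsv"
        )
        group_outputs = []
        if sets_path.exists():
            sets = load_genesets(sets_path)
            alternative = config.groups.get("alternative", "less")
            rows = []
            corrected = (
                length_corrected_test(
                    table["dte_log2"], lengths.loc[table.index], sets, alternative
                )
                if config.groups.get("length_correct", True)
                else None
            )
            for s in sets:
                res = mwu_geneset_test(table["dte_log2"], s, alternative)
                row = {
                    "set": s.name,
                    "n_in": res.n_in,
                    "n_out": res.n_out,
                    "U": res.u,
                    "p": res.p,
                    "p_other_side": res.p_other_side,
                    "median_shift": res.median_shift,
                }
                if corrected is not None:
                    row["p_length_corrected"] = corrected.tests[s.name].p
                rows.append(row)
            groups_path = outdir / "groups.tsv"
            pd.DataFrame(rows).to_csv(
                groups_path, sep="\t", index=False, float_format=_FLOAT_FMT
            )
            summary, _ = geneset_percent_summary(
                table["dte_percent"],
                lengths.loc[table.index],
                sets,
                min_size=int(config.groups.get("min_size", 21)),
            )
            summary_path = outdir / "groups_summary.tsv"
            summary.to_csv(summary_path, sep="\t", index=False, float_format=_FLOAT_FMT)
            group_outputs = [groups_path, summary_path]
    record("groups", t0, group_outputs, caught)

    # --- trace --------------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        trace_file = config.trace.get("input")
        trace_in = config.base_dir / trace_file if trace_file else outdir / "trace.csv"
        trace_obj = PolysomeTrace.from_csv(trace_in)
        peaks, ratios = quantify_trace(
            trace_obj,
            smooth_window=int(config.trace.get("smooth_window", 5)),
        )
        peaks_path = outdir / "peaks.tsv"
        peaks.to_frame().to_csv(peaks_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        ratios_path = outdir / "ratios.tsv"
        pd.DataFrame(
            [
                {
                    "ratio_60_40": ratios.ratio_60_40,
                    "ratio_p_m": ratios.ratio_p_m,
                    **{f"area_{k}": v for k, v in ratios.components.items()},
                }
            ]
        ).to_csv(ratios_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    record("trace", t0, [peaks_path, ratios_path], caught)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def manifest_checksums(manifest: dict) -> dict[str, str]:
    """Flat filename -> sha256 map (the deterministic part of a manifest)."""
    out: dict[str, str] = {}
    for stage in manifest["stages"].values():
        out.update(stage["outputs"])
    return out
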