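"""Orchestration of the sixteen-source study.

Builds the head model once, simulates every source with the same photon
budget, quantifies each run (layer percentages, depth-at-level, FWHM
curves) and collects the results into tidy tables.  Per-source seeds are
derived from the master seed by a documented splitting rule and recorded
in a run manifest; a study re-run from the same configuration reproduces
identical tables, and completed sources found in the output directory are
reused rather than re-simulated.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import axial_profile, depth_at_level, layer_percentages, width_profiles
from .sources import SOURCE_TYPES, SourceSpec, default_sources
from .tissue_model import (
    LabeledVolume,
    LayeredBrainSpec,
    OpticalPropertyTable,
    build_layered_volume,
    default_property_table,
)
from .transport import EnergyVolume, SimConfig, run_simulation

log = logging.getLogger("brainbeam")

#: photons per source for the named presets; `full` is the study scale
PRESETS = {"desk": 1_000_000, "standard": 10_000_000, "full": 100_000_000}

DEPTH_LEVELS = (0.01, 0.001, 0.0001)  # 1%, 0.1%, 0.01% of the column maximum


def per_source_seed(master_seed: int, source_index: int) -> int:
    """Seed-splitting rule: a fixed multiplicative hash of (master, index)."""
    return int((master_seed * 1_000_003 + source_index * 7_919 + 1) % (2**31 - 1))


@dataclass
class StudyConfig:
    brain_spec: LayeredBrainSpec = field(default_factory=LayeredBrainSpec)
    properties: OpticalPropertyTable = field(default_factory=default_property_table)
    sources: list = field(default_factory=default_sources)
    sim: SimConfig = field(default_factory=SimConfig)
    output_dir: str | None = None
    fwhm_depths_mm: tuple = tuple(np.round(np.arange(0.1, 14.05, 0.1), 1))
    save_volumes: bool = False

    def __post_init__(self):
        tags = [s.type_tag for s in self.sources]
        if len(tags) != len(set(tags)):
            raise ValueError("each source type may appear at most once in a study")

    @classmethod
    def preset(cls, name: str, seed: int = 0, **kwargs) -> "StudyConfig":
        sim = SimConfig(n_photons=PRESETS[name], rng_seed=seed)
        return cls(sim=sim, **kwargs)


@dataclass
class StudyTables:
    """Collected study results.

    ``fp`` / ``ap``: one row per source x layer (energy percentages);
    ``depths``: one row per source x level x energy kind;
    ``fwhm``: one row per source x depth x axis x energy kind;
    ``ledgers``: per-source energy bookkeeping.
    """

    fp: pd.DataFrame
    ap: pd.DataFrame
    depths: pd.DataFrame
    fwhm: pd.DataFrame
    ledgers: pd.DataFrame
    failures: dict = field(default_factory=dict)

    def percentages(self, kind: str = "fluence") -> pd.DataFrame:
        """Wide source-by-layer table of FP or AP."""
        table = self.fp if kind == "fluence" else self.ap
        return table.pivot(index="source", columns="layer", values="percent")

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("fp", "ap", "depths", "fwhm", "ledgers"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        payload = {name: getattr(self, name).to_dict("records") for name in ("fp", "ap", "depths")}
        (outdir / "tables.json").write_text(json.dumps(payload, indent=2))


def quantify_run(E: EnergyVolume, volume: LabeledVolume, fwhm_depths_mm) -> dict:
    """All quantification outputs for one simulated source."""
    out = {"source": E.source_tag}
    for kind, short in (("fluence", "FP"), ("absorption", "AP")):
        summary = layer_percentages(E, volume, kind=kind)
        out[short] = summary.percentages
        profile = axial_profile(E, kind=kind)
        out[f"depths_{kind}"] = [depth_at_level(profile, lv) for lv in DEPTH_LEVELS]
        out[f"fwhm_{kind}"] = width_profiles(E, fwhm_depths_mm, kind=kind)
    out["ledger"] = {
        "launched_energy": E.launched_energy,
        "escaped_fraction": E.escaped_energy,
        "residual_fraction": E.residual_energy,
        "absorbed_fraction": E.absorbed_energy,
        "roulette_net": E.roulette_net,
        "n_photons": E.n_photons,
        "rng_seed": E.rng_seed,
    }
    return out


def run_study(config: StudyConfig) -> StudyTables:
    """Simulate every configured source and assemble the study tables."""
    volume = build_layered_volume(config.brain_spec)
    config.properties.validate_against(volume)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    fp_rows, ap_rows, depth_rows, fwhm_rows, ledger_rows = [], [], [], [], []
    failures = {}
    manifest = {
        "master_seed": config.sim.rng_seed,
        "n_photons_per_source": config.sim.n_photons,
        "sources": {},
    }

    for idx, source in enumerate(config.sources):
        seed = per_source_seed(config.sim.rng_seed, idx)
        manifest["sources"][source.type_tag] = {"index": idx, "seed": seed}
        cache = outdir / f"{source.type_tag}_result.json" if outdir else None
        try:
            if cache and cache.exists():
                res = _load_cached(cache, seed, config.sim.n_photons)
            else:
                res = None
            if res is None:
                sim = replace(config.sim, rng_seed=seed)
                log.info("simulating %s (%d photons, seed %d)", source.type_tag, sim.n_photons, seed)
                E = run_simulation(volume, config.properties, source, sim)
                res = quantify_run(E, volume, config.fwhm_depths_mm)
                log.info(
                    "%s: escaped %.4f absorbed %.4f residual %.2e",
                    source.type_tag,
                    E.escaped_energy,
                    E.absorbed_energy,
                    E.residual_energy,
                )
                if cache:
                    _save_cached(cache, res)
                if outdir and config.save_volumes:
                    E.save(outdir / source.type_tag)
        except Exception as exc:  # keep going; report at the end
            log.error("source %s failed: %s", source.type_tag, exc)
            failures[source.type_tag] = "".join(
                traceback.format_exception_only(type(exc), exc)
            ).strip()
            continue

        for layer in range(1, 5):
            fp_rows.append({"source": source.type_tag, "layer": layer, "percent": res["FP"][layer - 1]})
            ap_rows.append({"source": source.type_tag, "layer": layer, "percent": res["AP"][layer - 1]})
        for kind in ("fluence", "absorption"):
            for lv, dres in zip(DEPTH_LEVELS, res[f"depths_{kind}"]):
                depth_rows.append(
                    {
                        "source": source.type_tag,
                        "kind": kind,
                        "level": lv,
                        "depth_mm": dres.depth_mm,
                        "reached": dres.reached,
                        "noise_guard_ok": dres.noise_guard_ok,
                        "rel_se_at_depth": dres.rel_se_at_depth,
                    }
                )
            wp = res[f"fwhm_{kind}"]
            for d, wx, wy in zip(wp.depths_mm, wp.fwhm_x_mm, wp.fwhm_y_mm):
                fwhm_rows.append(
                    {"source": source.type_tag, "kind": kind, "depth_mm": d, "axis": "x", "fwhm_mm": wx}
                )
                fwhm_rows.append(
                    {"source": source.type_tag, "kind": kind, "depth_mm": d, "axis": "y", "fwhm_mm": wy}
                )
        ledger_rows.append({"source": source.type_tag, **res["ledger"]})

    tables = StudyTables(
        fp=pd.DataFrame(fp_rows),
        ap=pd.DataFrame(ap_rows),
        depths=pd.DataFrame(depth_rows),
        fwhm=pd.DataFrame(fwhm_rows),
        ledgers=pd.DataFrame(ledger_rows),
        failures=failures,
    )
    if outdir:
        tables.save(outdir)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if failures:
        raise StudyError(f"{len(failures)} source(s) failed: {sorted(failures)}", tables)
    return tables


def plot_study(tables: StudyTables, outdir) -> list:
    """Write summary figures: per-layer FP/AP bars and FWHM-vs-depth curves.

    Returns the paths written.  Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, axes = plt.subplots(1, 2, figsize=(13, 4), sharey=False)
    for ax, kind, table in zip(axes, ("FP", "AP"), (tables.fp, tables.ap)):
        wide = table.pivot(index="source", columns="layer", values="percent")
        wide.plot.bar(ax=ax, stacked=True, legend=kind == "FP")
        ax.set_ylabel(f"{kind} per layer [%]")
        ax.set_xlabel("")
    fig.tight_layout()
    path = outdir / "layer_percentages.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    sel = tables.fwhm.query("kind == 'fluence' and axis == 'x'")
    for source, group in sel.groupby("source"):
        ax.plot(group["depth_mm"], group["fwhm_mm"], lw=1, label=source)
    ax.set_xlabel("depth [mm]")
    ax.set_ylabel("FWHM of fluence, x cut [mm]")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    path = outdir / "fwhm_vs_depth.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths


class StudyError(RuntimeError):
    """Raised when one or more sources failed; partial tables are attached."""

    def __init__(self, msg, tables):
        super().__init__(msg)
        self.tables = tables


def top_k(values: pd.Series | dict, k: int) -> list:
    """Top-k keys by value, stable descending (ties keep input order)."""
    if isinstance(values, dict):
        values = pd.Series(values)
    if values.empty:
        raise ValueError("empty ranking slice")
    if k > len(values):
        raise ValueError("k exceeds the number of entries")
    order = sorted(range(len(values)), key=lambda i: (-values.iloc[i], i))
    return [values.index[i] for i in order[:k]]


# -- per-source result cache (resumable studies) ----------------------------

def _dres_to_dict(d):
    return {
        "depth_mm": d.depth_mm,
        "reached": d.reached,
        "level": d.level,
        "noise_guard_ok": d.noise_guard_ok,
        "rel_se_at_depth": None if np.isnan(d.rel_se_at_depth) else d.rel_se_at_depth,
    }


def _save_cached(path: Path, res: dict) -> None:
    from .quantify import WidthProfile

    payload = {
        "source": res["source"],
        "FP": list(res["FP"]),
        "AP": list(res["AP"]),
        "ledger": res["ledger"],
    }
    for kind in ("fluence", "absorption"):
        payload[f"depths_{kind}"] = [_dres_to_dict(d) for d in res[f"depths_{kind}"]]
        wp = res[f"fwhm_{kind}"]
        payload[f"fwhm_{kind}"] = {
            "depths_mm": list(wp.depths_mm),
            "fwhm_x_mm": [None if np.isnan(v) else v for v in wp.fwhm_x_mm],
            "fwhm_y_mm": [None if np.isnan(v) else v for v in wp.fwhm_y_mm],
        }
    path.write_text(json.dumps(payload))


def _load_cached(path: Path, seed: int, n_photons: int):
    from .quantify import DepthResult, WidthProfile

    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError):
        return None
    ledger = payload.get("ledger", {})
    if ledger.get("rng_seed") != seed or ledger.get("n_photons") != n_photons:
        return None  # stale cache from a different configuration
    res = {
        "source": payload["source"],
        "FP": np.array(payload["FP"]),
        "AP": np.array(payload["AP"]),
        "ledger": ledger,
    }
    for kind in ("fluence", "absorption"):
        res[f"depths_{kind}"] = [
            DepthResult(
                depth_mm=d["depth_mm"],
                reached=d["reached"],
                level=d["level"],
                noise_guard_ok=d["noise_guard_ok"],
                rel_se_at_depth=float("nan") if d["rel_se_at_depth"] is None else d["rel_se_at_depth"],
            )
            for d in payload[f"depths_{kind}"]
        ]
        wp = payload[f"fwhm_{kind}"]
        res[f"fwhm_{kind}"] = WidthProfile(
            depths_mm=np.array(wp["depths_mm"]),
            fwhm_x_mm=np.array([np.nan if v is None else v for v in wp["fwhm_x_mm"]]),
            fwhm_y_mm=np.array([np.nan if v is None else v for v in wp["fwhm_y_mm"]]),
            source_kind=kind,
        )
    return res
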