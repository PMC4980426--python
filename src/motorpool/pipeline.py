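"""End-to-end runs from a single config, with logged provenance.

Two entry points mirror the two halves of the analysis:

* :func:`run_phase_pipeline` — (simulate or load traces) → per-pair
  multitaper coherency at the reference's dominant frequency → per-condition
  phase samples → circular summaries and the requested angular tests.
* :func:`run_connectome_pipeline` — (simulate or load a synapse-count
  graph) → pairwise shared-input summaries and contribution correlations →
  candidate-interneuron screening with the thresholds echoed into the report.

Reports are plain dicts (JSON-serializable) carrying the exact config, the
seed and the package version, so every printed number is reproducible; a
light structural schema validator is included.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circular import (
    AngleSample,
    PairedAngleSample,
    circular_mean,
    hotelling_paired_test,
    watson_williams_test,
)
from .connectome import (
    ConnectomeGraph,
    divergent_synapse_fraction,
    paired_contribution_correlation,
    percent,
    screen_candidates,
    shared_input_summary,
)
from .spectral import MultitaperConfig, multitaper_coherency
from .synth import (
    PeristalsisConfig,
    SyntheticConnectomeConfig,
    simulate_connectome,
    simulate_peristalsis,
)
from .traces import TimeSeriesTrace, read_traces_csv

__all__ = [
    "ConfigError",
    "load_config",
    "run_phase_pipeline",
    "run_connectome_pipeline",
    "validate_report",
    "PHASE_REPORT_SCHEMA",
    "CONNECTOME_REPORT_SCHEMA",
]

log = logging.getLogger("motorpool")


class ConfigError(ValueError):
    """Raised for invalid or incomplete pipeline configuration."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg


def _spectral_config(cfg: dict) -> MultitaperConfig:
    block = dict(cfg.get("spectral", {}))
    if "frequency_band" in block and block["frequency_band"] is not None:
        block["frequency_band"] = tuple(block["frequency_band"])
    return MultitaperConfig(**block)


def _condition_traces(name: str, block: dict, seed: int | None) -> dict[str, TimeSeriesTrace]:
    if "traces" in block:
        return read_traces_csv(block["traces"])
    if "simulate" in block:
        params = dict(block["simulate"])
        if seed is not None and "seed" not in params:
            params["seed"] = seed
        sim = simulate_peristalsis(PeristalsisConfig(**params))
        return {m.label: m.trace for m in sim}
    raise ConfigError(f"condition {name!r}: needs either 'traces' or 'simulate'")


def _pairs_for(traces: dict[str, TimeSeriesTrace], cfg: dict) -> list[tuple[str, str]]:
    """Resolve (reference, test) label pairs for one condition."""
    if "pairs" in cfg:
        pairs = [tuple(p) for p in cfg["pairs"]]
        for ref, test in pairs:
            for lbl in (ref, test):
                if lbl not in traces:
                    raise ConfigError(f"pair label {lbl!r} not among traces")
        return pairs
    pairing = cfg.get("pairing", "segment")
    if pairing == "segment":
        ref_prefix = cfg.get("reference_prefix", "LO1")
        pairs = []
        for lbl in sorted(traces):
            if not lbl.startswith(ref_prefix + "_"):
                continue
            suffix = lbl.split("_", 1)[1]
            mates = [
                t for t in sorted(traces)
                if t.endswith("_" + suffix) and t != lbl
            ]
            pairs.extend((lbl, m) for m in mates)
        if not pairs:
            raise ConfigError(
                f"no segment pairs found for reference prefix {ref_prefix!r}"
            )
        return pairs
    if pairing == "reference":
        ref = cfg.get("reference")
        if ref is None or ref not in traces:
            raise ConfigError(f"reference label {ref!r} missing from traces")
        return [(ref, t) for t in sorted(traces) if t != ref]
    raise ConfigError(f"unknown pairing mode {pairing!r}")


def run_phase_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run coherency + circular-statistics analysis from a config dict.

    Per-pair failures are recorded in the report's ``errors`` list and the
    run continues.
    """
    seed = config.get("seed")
    mt_config = _spectral_config(config)
    conditions_cfg = config.get("conditions")
    if not conditions_cfg:
        raise ConfigError("config needs a 'conditions' mapping")

    report: dict = {
        "pipeline": "phase",
        "version": __version__,
        "seed": seed,
        "config": config,
        "conditions": {},
        "tests": [],
        "errors": [],
    }
    condition_phases: dict[str, list[float]] = {}
    for name, block in conditions_cfg.items():
        traces = _condition_traces(name, block, seed)
        pairs = _pairs_for(traces, {**config, **block})
        pair_rows = []
        phases = []
        for ref_label, test_label in pairs:
            try:
                res = multitaper_coherency(traces[ref_label], traces[test_label], mt_config)
            except Exception as exc:  # keep going across segments
                report["errors"].append(
                    {"condition": name, "pair": [ref_label, test_label], "error": str(exc)}
                )
                continue
            pair_rows.append(
                {
                    "reference": ref_label,
                    "test": test_label,
                    "dominant_frequency_hz": res.dominant_frequency,
                    "magnitude": res.magnitude_at_dominant,
                    "phase_deg": res.phase_at_dominant,
                    "threshold": res.null_threshold,
                    "significant": res.is_significant,
                }
            )
            phases.append(res.phase_at_dominant)
        summary = None
        if phases:
            cs = circular_mean(AngleSample(np.array(phases), label=name))
            summary = {
                "mean_phase_deg": cs.mean_direction,
                "resultant_length": cs.resultant_length,
                "ci95_halfwidth_deg": cs.ci95_halfwidth,
                "n": cs.n,
                "mean_defined": cs.mean_defined,
            }
        report["conditions"][name] = {"pairs": pair_rows, "circular_summary": summary}
        condition_phases[name] = phases

    for test_name in config.get("tests", []):
        names = list(condition_phases)
        if test_name == "hotelling_paired":
            if len(names) != 2:
                raise ConfigError("hotelling_paired needs exactly 2 conditions")
            a, b = (condition_phases[n] for n in names)
            if len(a) != len(b):
                raise ConfigError("hotelling_paired needs matched pair counts")
            res = hotelling_paired_test(
                PairedAngleSample(
                    AngleSample(np.array(a), names[0]), AngleSample(np.array(b), names[1])
                )
            )
        elif test_name == "watson_williams":
            groups = [AngleSample(np.array(condition_phases[n]), n) for n in names]
            res = watson_williams_test(groups)
        else:
            raise ConfigError(f"unknown test {test_name!r}")
        report["tests"].append(
            {
                "test": res.test_name,
                "statistic": res.statistic,
                "df": list(res.df),
                "p_value": res.p_value,
                "flags": list(res.flags),
                "conditions": names,
                "multiple_comparison_correction": "none",
            }
        )

    if out_dir is not None:
        _write_phase_outputs(report, out_dir)
    return report


def _write_phase_outputs(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "phase_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    rows = [
        {"condition": name, **row}
        for name, block in report["conditions"].items()
        for row in block["pairs"]
    ]
    if rows:
        pd.DataFrame(rows).to_csv(out / "phase_pairs.csv", index=False)
    log.info("phase pipeline report written to %s", out)


def _resolve_pool(graph: ConnectomeGraph, spec) -> set[str]:
    """A pool is either an explicit id list or a pool name from the
    annotation table."""
    if isinstance(spec, str):
        ids = graph.neurons_in_pool(spec)
        if not ids:
            raise ConfigError(f"no neurons annotated with pool {spec!r}")
        return ids
    return set(spec)


def run_connectome_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run connectivity summaries + screening from a config dict."""
    if "graph" in config:
        block = config["graph"]
        graph = ConnectomeGraph.from_csv(block["neurons"], block["edges"])
    elif "simulate" in config:
        params = dict(config["simulate"])
        if config.get("seed") is not None and "seed" not in params:
            params["seed"] = config["seed"]
        graph = simulate_connectome(SyntheticConnectomeConfig(**params))
    else:
        raise ConfigError("config needs 'graph' (csv paths) or 'simulate'")

    report: dict = {
        "pipeline": "connectome",
        "version": __version__,
        "seed": config.get("seed"),
        "config": config,
        "pairs": [],
        "screen": None,
    }
    for pair in config.get("pairs", []):
        a, b = pair
        s = shared_input_summary(graph, a, b)
        r, n_shared = paired_contribution_correlation(graph, a, b)
        report["pairs"].append(
            {
                "neuron_a": a,
                "neuron_b": b,
                "shared_partner_count": s.shared_partner_count,
                "union_partner_count": s.union_partner_count,
                "shared_partner_fraction": s.shared_partner_fraction,
                "shared_partner_percent": s.shared_partner_percent,
                "shared_synapse_fraction_a": s.shared_synapse_fraction_a,
                "shared_synapse_fraction_b": s.shared_synapse_fraction_b,
                "divergent_synapse_fraction": divergent_synapse_fraction(graph, a, b),
                "contribution_pearson_r": r,
                "n_shared_for_r": n_shared,
            }
        )
    if "screen" in config and config["screen"] is not None:
        sc = config["screen"]
        target = _resolve_pool(graph, sc["target_pool"])
        excluded = _resolve_pool(graph, sc.get("excluded_pool", []))
        min_synapses = int(sc.get("min_synapses", 35))
        min_fraction = float(sc.get("min_fraction", 0.0275))
        hits = screen_candidates(
            graph,
            target,
            excluded,
            transmitter=sc.get("transmitter"),
            min_synapses=min_synapses,
            min_fraction=min_fraction,
        )
        from .connectome import input_fraction

        report["screen"] = {
            "target_pool": sorted(target),
            "excluded_pool": sorted(excluded),
            "transmitter": sc.get("transmitter"),
            "min_synapses": min_synapses,
            "min_fraction": min_fraction,
            "candidates": [
                {"neuron_id": h, "input_fraction": input_fraction(graph, h, target)}
                for h in hits
            ],
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "connectome_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        if report["pairs"]:
            pd.DataFrame(report["pairs"]).to_csv(out / "connectome_pairs.csv", index=False)
        graph.to_graphml(out / "connectome.graphml")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# --- minimal structural report schemas --------------------------------

PHASE_REPORT_SCHEMA = {
    "type": "object",
    "required": ["pipeline", "version", "config", "conditions", "tests", "errors"],
    "properties": {
        "pipeline": {"type": "string"},
        "version": {"type": "string"},
        "conditions": {"type": "object"},
        "tests": {"type": "array"},
        "errors": {"type": "array"},
    },
}

CONNECTOME_REPORT_SCHEMA = {
    "type": "object",
    "required": ["pipeline", "version", "config", "pairs"],
    "properties": {
        "pipeline": {"type": "string"},
        "version": {"type": "string"},
        "pairs": {"type": "array"},
    },
}

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def validate_report(report: dict, schema: dict) -> None:
    """Check a report against a structural schema; raises ValueError."""
    expected = _TYPES[schema.get("type", "object")]
    if not isinstance(report, expected):
        raise ValueError(f"expected {schema['type']}, got {type(report).__name__}")
    for key in schema.get("required", []):
        if key not in report:
            raise ValueError(f"missing required report key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in report and report[key] is not None:
            validate_report(report[key], sub)
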