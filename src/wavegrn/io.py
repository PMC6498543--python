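"""Readers/writers for the pipeline's plain-text formats.

Formats: per-time-point cells×genes CSV with a JSON manifest
(snapshot datasets), genes×timepoints means CSV, gene-parameter CSV
(piecewise rates JSON-encoded per cell), topology JSON, wave-table CSV,
consensus interaction matrix CSV and YAML run configuration.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .model_core import GeneParams, STIMULUS_ID
from .simulator import SnapshotDataset
from .wave_analysis import WaveTable

__all__ = [
    "write_snapshot_dir",
    "read_snapshot_dir",
    "write_params_csv",
    "read_params_csv",
    "write_waves_csv",
    "read_waves_csv",
    "write_consensus_matrix",
    "load_run_config",
    "dump_run_config",
]

MANIFEST = "manifest.json"


def write_snapshot_dir(dataset: SnapshotDataset, path) -> Path:
    """One CSV per time point plus means tables and a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in dataset.timepoints:
        name = f"rna_t{t:g}.csv"
        dataset.rna[t].to_csv(path / name, index=False)
        entry = {"time_h": t, "rna": name}
        if dataset.protein is not None:
            pname = f"protein_t{t:g}.csv"
            dataset.protein[t].to_csv(path / pname, index=False)
            entry["protein"] = pname
        entries.append(entry)
    if dataset.mean_rna is not None:
        dataset.mean_rna.to_csv(path / "mean_rna.csv")
    if dataset.mean_protein is not None:
        dataset.mean_protein.to_csv(path / "mean_protein.csv")
    with open(path / MANIFEST, "w") as fh:
        json.dump({"timepoints": entries}, fh, indent=2)
    return path


def read_snapshot_dir(path) -> SnapshotDataset:
    """Load a snapshot directory written by :func:`write_snapshot_dir`.

    Validates that gene columns agree across time points and that every
    manifest entry resolves to a file; extra unlisted CSVs are ignored
    with a warning.
    """
    path = Path(path)
    with open(path / MANIFEST) as fh:
        manifest = json.load(fh)
    rna, protein = {}, {}
    timepoints = []
    listed = {MANIFEST, "mean_rna.csv", "mean_protein.csv"}
    genes = None
    for entry in manifest["timepoints"]:
        t = float(entry["time_h"])
        timepoints.append(t)
        f = path / entry["rna"]
        listed.add(entry["rna"])
        if not f.exists():
            raise FileNotFoundError(f"manifest lists missing time point file {f}")
        df = pd.read_csv(f)
        if genes is None:
            genes = list(df.columns)
        elif list(df.columns) != genes:
            bad = sorted(set(df.columns) ^ set(genes))
            raise ValueError(f"gene sets differ across time points: {bad}")
        rna[t] = df
        if "protein" in entry:
            listed.add(entry["protein"])
            protein[t] = pd.read_csv(path / entry["protein"])
    extra = {p.name for p in path.glob("*.csv")} - listed
    if extra:
        warnings.warn(f"ignoring unlisted files in {path}: {sorted(extra)}")
    mean_rna = mean_protein = None
    if (path / "mean_rna.csv").exists():
        mean_rna = pd.read_csv(path / "mean_rna.csv", index_col=0)
        mean_rna.columns = mean_rna.columns.astype(float)
    if (path / "mean_protein.csv").exists():
        mean_protein = pd.read_csv(path / "mean_protein.csv", index_col=0)
        mean_protein.columns = mean_protein.columns.astype(float)
    return SnapshotDataset(
        timepoints=timepoints,
        rna=rna,
        protein=protein or None,
        mean_rna=mean_rna,
        mean_protein=mean_protein,
    )


# -- gene parameter tables --------------------------------------------------

_RATE_COLS = ("d0", "s1", "d1")


def write_params_csv(params: dict[str, GeneParams], path) -> None:
    rows = []
    for g in params.values():
        d = g.to_dict()
        for c in _RATE_COLS:
            d[c] = json.dumps(d[c])
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_params_csv(path) -> dict[str, GeneParams]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        d = row.dropna().to_dict()
        for c in _RATE_COLS:
            d[c] = json.loads(d[c])
        gp = GeneParams.from_dict(d)
        out[gp.gene_id] = gp
    return out


def write_waves_csv(waves: WaveTable, path) -> None:
    waves.to_frame().to_csv(path, index=False)


def read_waves_csv(path) -> WaveTable:
    return WaveTable.from_frame(pd.read_csv(path))


def write_consensus_matrix(candidates, path) -> pd.DataFrame:
    """Edge frequencies across candidates, regulators×targets, in percent.

    Rows are regulators with the stimulus first; columns are targets.
    Entry (r, c) is the percentage of candidates carrying the edge
    r → c, whatever its sign.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    gene_ids = sorted({g for c in candidates for g in c.topology.gene_ids})
    regs = [STIMULUS_ID] + gene_ids
    mat = pd.DataFrame(0.0, index=regs, columns=gene_ids)
    for c in candidates:
        for (reg, tgt) in c.topology.theta:
            mat.loc[reg, tgt] += 1.0
    mat *= 100.0 / len(candidates)
    mat.to_csv(path)
    return mat


# -- run configuration ------------------------------------------------------

DEFAULT_RUN_CONFIG = {
    "simulation": {
        "dt": 0.5,
        "burn_in_start": -60.0,
        "stimulus_amplitude": 1000.0,
        "n_cells": 500,
    },
    "estimation": {
        "kon_min": 0.001,
        "bootstrap_samples": 1000,
        "percentile": 95.0,
        "cell_cycle_h": 20.0,
        "h_fraction": 0.25,
    },
    "waves": {
        "slope_threshold": 0.2,
        "variation_threshold": 0.2,
    },
    "inference": {
        "early_threshold_h": 5.0,
        "maybe_early_threshold_h": 7.0,
        "window_normal": [-20.0, 30.0],
        "window_autofeedback": [-30.0, 50.0],
        "beam_width": 8,
        "calibration_budget": 12,
        "n_cells_calibration": 200,
    },
}


def load_run_config(path=None) -> dict:
    """Defaults, deep-merged with overrides from a YAML file when given."""
    cfg = json.loads(json.dumps(DEFAULT_RUN_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    _validate_run_config(cfg)
    return cfg


def _validate_run_config(cfg: dict) -> None:
    if cfg["simulation"]["dt"] <= 0:
        raise ValueError("simulation.dt must be positive")
    if cfg["simulation"]["burn_in_start"] >= 0:
        raise ValueError("simulation.burn_in_start must be negative")
    if cfg["inference"]["beam_width"] < 1:
        raise ValueError("inference.beam_width must be >= 1")


def dump_run_config(cfg: dict, path) -> None:
    """Write the exact resolved configuration next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
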