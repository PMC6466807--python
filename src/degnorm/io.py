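"""Serialization and configuration: TSV tables, coverage archives, run logs.

All tables are UTF-8, tab-delimited with a header row and gene_id as the
first column.  Coverage matrices travel as a compressed array archive
(``coverage.npz`` keyed by gene_id) next to a ``counts.tsv`` and a
``samples.json`` fixing the sample order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from degnorm.coverage import CoverageMatrix

__all__ = [
    "RunConfig",
    "load_config",
    "read_counts_tsv",
    "write_matrix_tsv",
    "save_coverage_dir",
    "load_coverage_dir",
    "write_run_log",
]


@dataclass
class RunConfig:
    """Validated tunables of the DegNorm pipeline."""

    max_iter: int = 5
    rho_max: float = 0.9
    n_bins: int = 20
    di_stop: float = 0.1
    max_drop_frac: float = 0.8
    nmf_max_iter: int = 100
    nmf_tol: float = 1e-5
    tol_s: float = 1e-3
    tol_rho: float = 1e-3
    depth_method: str = "adjusted_total"
    min_count: int = 1
    min_max_coverage: float = 5.0
    seed: int = 0

    def __post_init__(self):
        checks = [
            (self.max_iter >= 1, "max_iter must be >= 1"),
            (0 < self.rho_max < 1, "rho_max must be in (0, 1)"),
            (self.n_bins >= 1, "n_bins must be >= 1"),
            (0 <= self.di_stop < 1, "di_stop must be in [0, 1)"),
            (0 < self.max_drop_frac <= 1, "max_drop_frac must be in (0, 1]"),
            (self.nmf_max_iter >= 1, "nmf_max_iter must be >= 1"),
            (self.nmf_tol > 0, "nmf_tol must be positive"),
            (self.tol_s > 0 and self.tol_rho > 0, "tolerances must be positive"),
            (self.depth_method in ("adjusted_total", "upper_quartile"),
             "depth_method must be 'adjusted_total' or 'upper_quartile'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)


def load_config(path: str, cls=RunConfig):
    """Load a YAML mapping into a config dataclass; unknown keys are an
    error, not silently defaulted."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a key/value mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - fields)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    for key in ("depth_range", "gene_length_range", "nb_log10_mean",
                "nb_log10_mean_range", "nb_disp_trend", "mix_components",
                "mix_mean_range", "mix_sd_range", "deg_iv_offset_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return cls(**raw)


def read_counts_tsv(path: str) -> pd.DataFrame:
    """Gene x sample count table; duplicate gene ids or non-numeric cells
    are errors."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene_id(s) in {path}: {dups[:5]}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in {path} at gene {row!r}, sample {col!r}"
            )
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str, sig_digits: int | None = None) -> None:
    df = df.copy()
    df.index.name = df.index.name or "gene_id"
    fmt = f"%.{sig_digits}g" if sig_digits else None
    df.to_csv(path, sep="\t", float_format=fmt)


def save_coverage_dir(coverages: list[CoverageMatrix], out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "coverage.npz", **{c.gene_id: c.F for c in coverages})
    samples = coverages[0].samples
    counts = pd.DataFrame(
        np.stack([c.X for c in coverages]),
        index=pd.Index([c.gene_id for c in coverages], name="gene_id"),
        columns=samples,
    )
    write_matrix_tsv(counts, out / "counts.tsv")
    (out / "samples.json").write_text(json.dumps(list(samples)))


def load_coverage_dir(
    in_dir: str, min_count: int = 1, min_max_coverage: float = 5.0
) -> list[CoverageMatrix]:
    src = Path(in_dir)
    counts = read_counts_tsv(src / "counts.tsv")
    samples = json.loads((src / "samples.json").read_text())
    out = []
    with np.load(src / "coverage.npz") as npz:
        for gid in counts.index:
            F = npz[gid]
            X = counts.loc[gid].to_numpy()
            active = bool((X >= min_count).all() and F.max() >= min_max_coverage)
            out.append(CoverageMatrix(gid, samples, F, X, active=active))
    return out


def write_run_log(path: str, config, extra: dict | None = None) -> None:
    from degnorm import __version__

    payload = {
        "version": __version__,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
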