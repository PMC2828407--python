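"""File formats: census CSV, chains CSV, summary JSON, flat config files.

All CSV outputs start with ``#``-prefixed metadata lines recording the
seed and a hash of the generating configuration, so a file identifies
the run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import McmcConfig, PosteriorChains
from .rates import CountSeries, StageCounts, ValidationError

COUNT_COLUMNS = ("year", "J1_obs", "J2_obs", "S_obs", "A_obs")

#: keys accepted in flat config files (fail-fast on anything else)
CONFIG_KEYS = {
    # sampler
    "n_iterations": int, "n_chains": int, "burn_in": int, "thin": int,
    "proposal_scale": float, "latent_width": int, "latent_sweeps": int,
    "scale_step": float, "scale_moves": int, "seed": int,
    # scenario
    "j1": float, "j2": float, "p1": float, "s": float, "p2": float,
    "a": float, "f": float, "p_obs": float,
    "initial_J2": int, "initial_S": int, "initial_A": int,
    "n_years": int, "first_year": int, "juvenile_sex_split": float,
}


def config_hash(obj) -> str:
    """Short stable hash of a configuration object or mapping."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _metadata_lines(seed=None, config=None, extra=None) -> list[str]:
    lines = []
    if seed is not None:
        lines.append(f"# seed = {seed}")
    if config is not None:
        lines.append(f"# config_hash = {config_hash(config)}")
    if extra:
        for k, v in extra.items():
            lines.append(f"# {k} = {v}")
    return lines


def write_counts(series: CountSeries, path, seed=None, config=None) -> None:
    path = Path(path)
    lines = _metadata_lines(seed, config,
                            {"label": series.label} if series.label else None)
    with path.open("w") as fh:
        for line in lines:
            fh.write(line + "\n")
        series.to_dataframe().to_csv(fh, index=False)


def read_counts(path) -> CountSeries:
    """Parse and validate a census CSV (header year,J1_obs,J2_obs,S_obs,A_obs).

    Errors name the offending line; year gaps name the missing year.
    """
    path = Path(path)
    label = ""
    with path.open() as fh:
        raw = fh.readlines()
    body_start = 0
    for line in raw:
        if line.startswith("#"):
            body_start += 1
            if "label =" in line:
                label = line.split("label =", 1)[1].strip()
        else:
            break
    header = raw[body_start].strip().split(",") if body_start < len(raw) else []
    if tuple(header) != COUNT_COLUMNS:
        raise ValidationError(
            f"{path}: expected header {','.join(COUNT_COLUMNS)}; "
            f"got {raw[body_start].strip() if header else '<empty file>'}")
    years, counts = [], []
    for lineno, line in enumerate(raw[body_start + 1:],
                                  start=body_start + 2):
        line = line.strip()
        if not line:
            continue
        cells = line.split(",")
        if len(cells) != 5:
            raise ValidationError(
                f"{path}:{lineno}: expected 5 cells, got {len(cells)}")
        try:
            values = [int(c) for c in cells]
        except ValueError as err:
            raise ValidationError(
                f"{path}:{lineno}: non-integer cell ({err})") from None
        if any(v < 0 for v in values[1:]):
            raise ValidationError(f"{path}:{lineno}: negative count")
        years.append(values[0])
        counts.append(StageCounts(*values[1:]))
    if not years:
        raise ValidationError(f"{path}: no data rows")
    for a, b in zip(years, years[1:]):
        if b != a + 1:
            raise ValidationError(
                f"{path}: missing census year {a + 1}")
    return CountSeries(tuple(years), tuple(counts), label=label)


def write_chains(chains: PosteriorChains, path, seed=None) -> None:
    path = Path(path)
    cfg = chains.config
    with path.open("w") as fh:
        for line in _metadata_lines(
                seed if seed is not None
                else (cfg.seed if cfg else None), cfg):
            fh.write(line + "\n")
        chains.to_dataframe().to_csv(fh, index=False)


def read_chains(path) -> PosteriorChains:
    df = pd.read_csv(path, comment="#")
    return PosteriorChains.from_dataframe(df)


def write_summary_json(summary: dict, path, seed=None, config=None) -> None:
    meta = {}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_hash"] = config_hash(config)
    payload = {"metadata": meta, **summary}

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return None if np.isnan(o) else float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default,
                                     allow_nan=False) + "\n")


def read_config(path) -> dict:
    """Parse a flat ``key = value`` config file; unknown keys are errors."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(),
                                  start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(
                f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in CONFIG_KEYS:
            raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            out[key] = CONFIG_KEYS[key](value.strip())
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: bad value for {key!r}") from None
    return out


def mcmc_config_from(options: dict) -> McmcConfig:
    fields = {f.name for f in dataclasses.fields(McmcConfig)}
    return McmcConfig(**{k: v for k, v in options.items() if k in fields})
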