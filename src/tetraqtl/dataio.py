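"""Reading and writing pseudotest-backcross datasets and result objects.

Native formats are TSV for tabular data and JSON for structured results.
Dataset files carry one row per individual with columns ``id``,
``marker`` (gamete genotype token, e.g. ``M1M3`` or ``1/3``), optional
``qtl_true`` and ``phenotype``; marker allele order is canonicalized on
input (lowest allele first).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .em import FitResult
from .gametes import GAMETE_PAIRS, gamete_labels
from .simulate import BackcrossDataset, ReplicationSummary

__all__ = [
    "parse_genotype_token",
    "read_dataset",
    "write_dataset",
    "write_results",
]

_PAIR_INDEX = {frozenset(p): i for i, p in enumerate(GAMETE_PAIRS)}
_TOKEN_RE = re.compile(
    r"^(?:[A-Za-z](?P<a1>[1-4])[A-Za-z](?P<a2>[1-4])|(?P<b1>[1-4])/(?P<b2>[1-4]))$")


def parse_genotype_token(token: str) -> int:
    """Canonical gamete index (0..9) for a token like ``'M3M1'`` or ``'3/1'``.

    Allele order within the pair is irrelevant (unordered genotypes).
    """
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ValueError(f"unrecognized genotype token {token!r}")
    a = int(m.group("a1") or m.group("b1")) - 1
    b = int(m.group("a2") or m.group("b2")) - 1
    return _PAIR_INDEX[frozenset((a, b))]


def read_dataset(path) -> BackcrossDataset:
    """Load a TSV dataset, validating tokens and phenotypes row by row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "marker", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    markers = np.empty(len(df), dtype=np.int64)
    phenos = np.empty(len(df), dtype=float)
    qtl = None
    if "qtl_true" in df.columns:
        qtl = np.empty(len(df), dtype=np.int64)
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            markers[i] = parse_genotype_token(row.marker)
        except ValueError as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from None
        if qtl is not None:
            try:
                qtl[i] = parse_genotype_token(row.qtl_true)
            except ValueError as exc:
                raise ValueError(f"{path}, line {line}: {exc}") from None
        try:
            phenos[i] = float(row.phenotype)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}, line {line}: non-numeric phenotype "
                f"{row.phenotype!r}") from None
        if not np.isfinite(phenos[i]):
            raise ValueError(f"{path}, line {line}: missing/non-finite phenotype")
    return BackcrossDataset(marker=markers, phenotype=phenos, qtl=qtl)


def write_dataset(data: BackcrossDataset, path) -> None:
    """Write a dataset as TSV with canonical genotype tokens."""
    data.to_frame().to_csv(path, sep="\t", index=False)


def _summary_table(summary: ReplicationSummary) -> pd.DataFrame:
    frame = summary.to_frame()
    sd_row = frame.loc["sd"].map(lambda v: f"({v:.3f})")
    out = frame.loc[["true", "mean"]].map(lambda v: f"{v:.3f}")
    out.loc["(sd)"] = sd_row
    return out


def write_results(result, path, format: str = "json") -> None:
    """Serialize a FitResult, ReplicationSummary or TestResult deterministically.

    ``format='json'`` writes every field; ``format='tsv'`` writes the
    tabular view (for a replication summary: true values, estimate means
    and SDs in the conventional three-row layout).
    """
    path = Path(path)
    if format == "json":
        payload = _to_payload(result)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    if format != "tsv":
        raise ValueError("format must be 'json' or 'tsv'")
    if isinstance(result, ReplicationSummary):
        _summary_table(result).to_csv(path, sep="\t")
    elif isinstance(result, FitResult):
        pd.Series(_flatten(result.to_dict())).to_csv(
            path, sep="\t", header=False)
    elif hasattr(result, "to_dict"):
        pd.Series(_flatten(result.to_dict())).to_csv(path, sep="\t", header=False)
    else:
        raise TypeError(f"cannot serialize {type(result).__name__} as TSV")


def _to_payload(result) -> dict:
    if isinstance(result, ReplicationSummary):
        cfg = result.config
        return {
            "config": {
                "n": cfg.n, "alpha": cfg.alpha, "beta": cfg.beta_effective,
                "r": cfg.r, "h2": cfg.h2, "seed": cfg.seed, "reps": cfg.reps,
                "effects": {k: float(v) for k, v in zip(
                    ("mu", "a1", "a2", "a3", "d12", "d13", "d14", "d23",
                     "d24", "d34"), cfg.effects.to_array())},
            },
            "n_converged": result.n_converged,
            "aligned_changed": result.aligned_changed,
            "mean": {k: _json_float(v) for k, v in result.mean().items()},
            "sd": {k: _json_float(v) for k, v in result.sd().items()},
        }
    if hasattr(result, "to_dict"):
        return result.to_dict()
    raise TypeError(f"cannot serialize {type(result).__name__}")


def _json_float(v):
    v = float(v)
    return None if not np.isfinite(v) else v


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, f"{key}."))
        elif isinstance(v, (list, tuple)):
            for i, x in enumerate(v):
                out[f"{key}.{i}"] = x
        else:
            out[key] = v
    return out
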