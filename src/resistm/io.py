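"""Reading and writing expression matrices, clinical tables and GMT
gene-set files.

Expression files are TSV/CSV with gene symbols in the first column and
sample ids in the header (genes in rows).  Clinical files carry columns
``sample_id, time, event, cms, icms, msi, fibrosis``; unknown subtype
strings map to ``"unlabeled"`` with a warning and the event column is
coerced strictly to {0, 1}.  GMT lines are ``name<TAB>description<TAB>
gene...``; signature direction is encoded by an ``_UP`` / ``_DN`` suffix
pair on the set name, so the built-in registry round-trips losslessly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import GeneSignature

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
]

_CMS_LEVELS = {"cms1": "CMS1", "cms2": "CMS2", "cms3": "CMS3", "cms4": "CMS4"}
_ICMS_LEVELS = {"icms2": "iCMS2", "icms3": "iCMS3"}
_MSI_LEVELS = {"msi": "MSI", "mss": "MSS"}
_FIBROSIS_LEVELS = {"fibrotic": "fibrotic", "non-fibrotic": "non-fibrotic",
                    "nonfibrotic": "non-fibrotic"}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path, duplicate_policy: str = "error") -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV/CSV.

    ``duplicate_policy``: ``"error"`` (default) rejects duplicated gene
    symbols naming them; ``"mean"`` collapses duplicates by averaging.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (missing header?)")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        if duplicate_policy == "mean":
            df = df.groupby(level=0, sort=False).mean()
        else:
            raise ValueError(f"{path}: duplicated gene symbol(s): {dup}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample id(s): {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric expression values: {err}") from err
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: expression contains non-finite values")
    # transposed-input heuristic: never auto-fixed, only a better message
    if df.shape[0] < df.shape[1] and df.columns.str.upper().str.isalpha().all() and \
            df.shape[0] <= 5:
        warnings.warn(
            f"{path}: matrix has far fewer rows than columns; expression is "
            "expected genes-in-rows — check orientation",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame(values, index=df.index, columns=df.columns.astype(str))


def write_expression(expr: pd.DataFrame, path) -> None:
    path = Path(path)
    expr.to_csv(path, sep=_sep_for(path), index_label="gene")


def _normalize_labels(col: pd.Series, mapping: dict, name: str, path) -> pd.Series:
    raw = col.fillna("unlabeled").astype(str)
    lowered = raw.str.strip().str.lower()
    out = lowered.map(mapping)
    unknown = out.isna() & (lowered != "unlabeled") & (lowered != "na")
    if unknown.any():
        warnings.warn(
            f"{path}: {int(unknown.sum())} unknown {name} label(s) "
            f"{sorted(raw[unknown].unique())} mapped to 'unlabeled'",
            UserWarning,
            stacklevel=3,
        )
    return out.fillna("unlabeled")


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical annotation table from TSV/CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s): {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique().tolist()
        raise ValueError(f"{path}: duplicated sample id(s): {dups}")
    times = pd.to_numeric(df["time"], errors="raise").astype(float)
    if not np.all(np.isfinite(times)) or (times < 0).any():
        raise ValueError(f"{path}: times must be finite and nonnegative")
    events = pd.to_numeric(df["event"], errors="raise")
    if not events.isin([0, 1]).all():
        bad = sorted(events[~events.isin([0, 1])].unique().tolist())
        raise ValueError(f"{path}: event values must be 0/1, found {bad}")
    out = pd.DataFrame({"sample_id": df["sample_id"], "time": times,
                        "event": events.astype(int)})
    for col, mapping in (("cms", _CMS_LEVELS), ("icms", _ICMS_LEVELS),
                         ("msi", _MSI_LEVELS), ("fibrosis", _FIBROSIS_LEVELS)):
        if col in df.columns:
            out[col] = _normalize_labels(df[col], mapping, col, path)
        else:
            out[col] = "unlabeled"
    return out


def write_clinical(clinical: pd.DataFrame, path) -> None:
    path = Path(path)
    clinical.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


def write_gmt(registry: dict[str, GeneSignature], path) -> None:
    """Write signatures as GMT; each directional arm becomes one set with
    an ``_UP`` / ``_DN`` suffix."""
    path = Path(path)
    with open(path, "w") as fh:
        for sig in registry.values():
            if sig.up_genes:
                fh.write("\t".join([f"{sig.name}_UP", sig.provenance or "na",
                                    *sig.up_genes]) + "\n")
            if sig.down_genes:
                fh.write("\t".join([f"{sig.name}_DN", sig.provenance or "na",
                                    *sig.down_genes]) + "\n")


def read_gmt(path) -> dict[str, GeneSignature]:
    """Read a GMT file into a signature registry.

    ``NAME_UP`` / ``NAME_DN`` lines are paired back into one signature
    ``NAME``; a set name without a direction suffix is treated as
    risk-up.  Malformed lines (< 3 tab-separated fields) raise with the
    line number.
    """
    path = Path(path)
    arms: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description, >=1 gene; got {len(fields)} field(s))"
                )
            raw_name, desc, genes = fields[0], fields[1], tuple(fields[2:])
            if raw_name.endswith("_UP"):
                name, arm = raw_name[:-3], "up"
            elif raw_name.endswith("_DN"):
                name, arm = raw_name[:-3], "down"
            else:
                name, arm = raw_name, "up"
            entry = arms.setdefault(name, {"up": (), "down": (), "desc": desc})
            if entry[arm]:
                raise ValueError(f"{path}:{lineno}: duplicate {arm}-arm for {name!r}")
            entry[arm] = genes
            if name not in order:
                order.append(name)
    return {
        name: GeneSignature(name, up_genes=arms[name]["up"],
                            down_genes=arms[name]["down"],
                            provenance=arms[name]["desc"])
        for name in order
    }
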