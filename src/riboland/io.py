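"""File formats: fitness tables, read-count tables, simulation traces.

The canonical interchange format is tab-separated text with
'#'-prefixed ``key=value`` metadata lines before the header row —
diff-able, durable and round-trippable.  A one-way converter ingests the
spreadsheet layout in which dual-function fitness measurements are
commonly published (one row per genotype, fitness and replicate-error
columns for each function).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_space import index_to_genotype, validate_genotype
from .landscape import Landscape

__all__ = [
    "read_fitness_table",
    "write_fitness_table",
    "landscapes_from_table",
    "table_from_landscapes",
    "read_count_table",
    "write_count_table",
    "convert_s1_spreadsheet",
    "write_trace",
    "read_trace",
]

FITNESS_COLUMNS = ["genotype", "hdv_fitness", "hdv_delta", "ligase_fitness", "ligase_delta"]


def _read_meta(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n_meta


def read_fitness_table(
    path, require_complete: bool = True, fill_missing: bool = False
) -> pd.DataFrame:
    """Read and validate a dual-function fitness table.

    Columns: genotype, hdv_fitness, hdv_delta, ligase_fitness,
    ligase_delta.  Validation rejects duplicate genotypes, malformed
    genotype strings and negative or non-finite numbers.  In complete
    mode the table must cover all 2^L genotypes; with ``fill_missing``
    absent genotypes are appended with fitness 0 instead.  Metadata from
    '#' header lines lands in ``result.attrs["meta"]``.
    """
    path = Path(path)
    meta, _ = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"genotype": str})
    missing_cols = set(FITNESS_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"fitness table missing columns: {sorted(missing_cols)}")
    if df.empty:
        raise ValueError("fitness table is empty")
    L = len(df["genotype"].iloc[0])
    for i, g in enumerate(df["genotype"]):
        try:
            validate_genotype(g, L=L)
        except ValueError as e:
            raise ValueError(f"malformed row {i + 2}: {e}") from e
    dup = df["genotype"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate genotype {df['genotype'][dup].iloc[0]!r}")
    num = df[FITNESS_COLUMNS[1:]].to_numpy(dtype=float)
    if not np.all(np.isfinite(num)) or np.any(num < 0):
        bad = int(np.flatnonzero(~np.isfinite(num).all(axis=1) | (num < 0).any(axis=1))[0])
        raise ValueError(f"non-finite or negative value in row {bad + 2}")
    n_expected = 1 << L
    if len(df) != n_expected:
        present = set(df["genotype"])
        missing = [
            index_to_genotype(i, L)
            for i in range(n_expected)
            if index_to_genotype(i, L) not in present
        ]
        if fill_missing:
            filler = pd.DataFrame(
                {
                    "genotype": missing,
                    "hdv_fitness": 0.0,
                    "hdv_delta": 0.0,
                    "ligase_fitness": 0.0,
                    "ligase_delta": 0.0,
                }
            )
            df = pd.concat([df, filler], ignore_index=True)
        elif require_complete:
            preview = ", ".join(missing[:3]) + ("..." if len(missing) > 3 else "")
            raise ValueError(
                f"incomplete table: {len(missing)} of {n_expected} genotypes "
                f"missing (e.g. {preview})"
            )
    df = df.sort_values("genotype", ignore_index=True)
    df.attrs["meta"] = meta
    return df


def write_fitness_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, columns=FITNESS_COLUMNS)


def landscapes_from_table(df: pd.DataFrame) -> tuple[Landscape, Landscape]:
    """Build the (hdv, ligase) Landscape pair from a complete fitness table."""
    L = len(df["genotype"].iloc[0])
    hdv = Landscape.from_mapping(
        dict(zip(df["genotype"], df["hdv_fitness"])),
        L=L,
        delta=dict(zip(df["genotype"], df["hdv_delta"])),
        name="hdv",
    )
    ligase = Landscape.from_mapping(
        dict(zip(df["genotype"], df["ligase_fitness"])),
        L=L,
        delta=dict(zip(df["genotype"], df["ligase_delta"])),
        name="ligase",
    )
    return hdv, ligase


def table_from_landscapes(hdv: Landscape, ligase: Landscape) -> pd.DataFrame:
    """Inverse of :func:`landscapes_from_table` (deltas default to 0)."""
    if hdv.L != ligase.L:
        raise ValueError("landscapes have different dimensions")
    n = hdv.n_genotypes
    zeros = np.zeros(n)
    df = pd.DataFrame(
        {
            "genotype": [index_to_genotype(i, hdv.L) for i in range(n)],
            "hdv_fitness": hdv.fitness,
            "hdv_delta": hdv.delta if hdv.delta is not None else zeros,
            "ligase_fitness": ligase.fitness,
            "ligase_delta": ligase.delta if ligase.delta is not None else zeros,
        }
    )
    return df.sort_values("genotype", ignore_index=True)


def read_count_table(path, assay: str) -> pd.DataFrame:
    """Read a long-format read-count table (TSV).

    assay="hdv" expects columns genotype, replicate, cleaved, uncleaved;
    assay="ligase" expects genotype, replicate, pre, post.
    """
    from .fitness_ingest import validate_read_counts

    cols = ("cleaved", "uncleaved") if assay == "hdv" else ("pre", "post")
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={"genotype": str})
    return validate_read_counts(df, cols)


def write_count_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


DEFAULT_S1_COLUMN_MAP = {
    "genotype": "genotype",
    "hdv_fitness": "hdv_fitness",
    "hdv_delta": "hdv_delta",
    "ligase_fitness": "ligase_fitness",
    "ligase_delta": "ligase_delta",
}


def convert_s1_spreadsheet(
    path,
    column_map: dict[str, str] | None = None,
    genotype_columns: list[str] | None = None,
    sheet_name=0,
) -> pd.DataFrame:
    """Convert a published dual-fitness spreadsheet to the canonical table.

    ``column_map`` maps canonical names to the spreadsheet's column
    headers (matched case-insensitively).  When the genotype is spread
    over one column per variable position, pass the ordered
    ``genotype_columns`` instead of a genotype entry in the map; the
    columns are concatenated position 0 first.  Missing delta columns
    convert with a warning and deltas set to 0.
    """
    import warnings

    cmap = dict(DEFAULT_S1_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_excel(Path(path), sheet_name=sheet_name)
    lower = {str(c).strip().lower(): c for c in raw.columns}

    def find(name: str):
        return lower.get(cmap[name].strip().lower())

    out = pd.DataFrame()
    if genotype_columns is not None:
        for c in genotype_columns:
            if c not in raw.columns:
                raise ValueError(f"genotype column {c!r} not found in spreadsheet")
        out["genotype"] = raw[genotype_columns].astype(str).agg("".join, axis=1)
    else:
        col = find("genotype")
        if col is None:
            raise ValueError(
                f"cannot map genotype column {cmap['genotype']!r}; "
                "pass column_map or genotype_columns"
            )
        gcol = raw[col].astype(str)
        # spreadsheet software often coerces all-digit genotype strings to
        # numbers, destroying leading zeros; restore by left-padding to the
        # longest observed length
        lengths = gcol.str.len()
        if lengths.nunique() > 1 and gcol.str.fullmatch(r"[01]+").all():
            warnings.warn(
                "genotype strings have unequal lengths (leading zeros likely "
                "stripped by the spreadsheet); left-padding with '0'"
            )
            gcol = gcol.str.zfill(int(lengths.max()))
        out["genotype"] = gcol
    for name in ("hdv_fitness", "ligase_fitness"):
        col = find(name)
        if col is None:
            raise ValueError(f"cannot map required column {cmap[name]!r}")
        out[name] = pd.to_numeric(raw[col])
    for name in ("hdv_delta", "ligase_delta"):
        col = find(name)
        if col is None:
            warnings.warn(f"column {cmap[name]!r} not found; deltas set to 0")
            out[name] = 0.0
        else:
            out[name] = pd.to_numeric(raw[col])
    out = out[FITNESS_COLUMNS]
    L = len(out["genotype"].iloc[0])
    for g in out["genotype"]:
        validate_genotype(g, L=L)
    return out.sort_values("genotype", ignore_index=True)


def write_trace(trace, path, extra_meta: dict | None = None) -> None:
    """Write a PopulationTrace as TSV with '#' metadata header lines."""
    cfg = trace.config
    meta = {
        "scenario": cfg.scenario,
        "target": cfg.target,
        "start_genotype": cfg.start_genotype,
        "N": cfg.N,
        "mu": cfg.mu,
        "generations": cfg.generations,
        "neutral_generations": cfg.neutral_generations,
        "beta_hdv": cfg.beta_hdv,
        "beta_ligase": cfg.beta_ligase,
        "seed": trace.seed,
        "n_unique_genotypes": trace.n_unique_genotypes,
        "summit_hit_generation": trace.summit_hit_generation,
    }
    meta.update(extra_meta or {})
    df = pd.DataFrame(
        {
            "generation": trace.generations,
            "mean_fitness": trace.mean_fitness,
            "mean_hdv": trace.mean_hdv,
            "mean_ligase": trace.mean_ligase,
            "diversity": trace.diversity,
        }
    )
    with open(Path(path), "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trace(path) -> pd.DataFrame:
    """Read a trace TSV; metadata lands in ``result.attrs["meta"]``."""
    path = Path(path)
    meta, _ = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    df.attrs["meta"] = meta
    return df
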