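"""Reading and writing of the pipeline's external formats.

Supported inputs are a probe-by-sample beta-value matrix (GEO
series-matrix text or a plain delimited table), an Illumina 450K-style
manifest table giving the probe-to-gene mapping, and a two-column
sample/group label table.  Outputs are tab-separated result tables plus a
JSON run summary.

Parsing is deliberately conservative: missing values are restricted to a
small token list ("", "NA", "N/A", "null", "NaN" and case variants),
decimal separators are always points, and probe order is preserved exactly
as found in the file so that downstream row indexing is reproducible.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

GROUP_LABELS = ("case", "control")

#: Tokens accepted as missing entries (series-matrix dialects vary).
MISSING_TOKENS = ("", "NA", "N/A", "na", "null", "NULL", "NaN", "nan")


def _first_duplicate(ids: Sequence[str]):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class BetaMatrix:
    """Probe-by-sample methylation beta values.

    ``values[i, j]`` is the beta value of probe ``feature_ids[i]`` in
    sample ``sample_ids[j]``; missing entries are NaN (allowed until the
    degenerate-probe filter runs).  ``groups`` maps every sample id to
    ``"case"`` or ``"control"`` and may be ``None`` until a label table is
    attached with :meth:`with_groups`.
    """

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    groups: dict | None = None

    def __post_init__(self):
        self.feature_ids = [str(x) for x in self.feature_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.feature_ids)
        if dup is not None:
            raise ValidationError(f"duplicate feature id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if self.groups is not None:
            self.groups = {str(k): str(v) for k, v in self.groups.items()}
            missing = [s for s in self.sample_ids if s not in self.groups]
            if missing:
                raise ValidationError(f"sample {missing[0]!r} has no group label")
            bad = {v for v in self.groups.values()} - set(GROUP_LABELS)
            if bad:
                raise ValidationError(
                    f"group labels must be in {GROUP_LABELS}, got {sorted(bad)}"
                )
            self.groups = {s: self.groups[s] for s in self.sample_ids}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_groups(self, groups: Mapping[str, str]) -> "BetaMatrix":
        return BetaMatrix(self.feature_ids, self.sample_ids, self.values.copy(), dict(groups))

    def select_features(self, keep: np.ndarray) -> "BetaMatrix":
        """Row subset by boolean mask or integer index, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        ids = [self.feature_ids[i] for i in idx]
        return BetaMatrix(ids, self.sample_ids, self.values[idx], self.groups)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class AnnotationMap:
    """Probe-id to official-gene-symbol mapping.

    A probe may map to zero genes (blank manifest cell), one gene, or
    several genes; a gene typically aggregates several probes, so the
    relation is many-to-many.
    """

    entries: dict

    def __post_init__(self):
        clean = {}
        for probe, genes in self.entries.items():
            gset = {str(g) for g in genes if str(g).strip() != ""}
            clean[str(probe)] = gset
        self.entries = clean

    def genes_for(self, probe: str) -> set:
        return self.entries.get(probe, set())

    def __len__(self) -> int:
        return len(self.entries)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_table(text: str, sep: str) -> pd.DataFrame:
    df = pd.read_csv(
        io.StringIO(text),
        sep=sep,
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype=str,
    )
    if df.index.isna().any() or any(str(c).startswith("Unnamed") for c in df.columns):
        raise FormatError("malformed header: empty sample or probe identifiers")
    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric matrix entry: {exc}") from exc
    ids = [str(i).strip('"') for i in df.index]
    samples = [str(c).strip('"') for c in df.columns]
    dup = _first_duplicate(ids)
    if dup is not None:
        raise ValidationError(f"duplicate probe id: {dup!r}")
    return BetaMatrix(ids, samples, values)


def read_beta_matrix(path, format: str | None = None) -> BetaMatrix:
    """Read a probe-by-sample beta matrix.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"series_matrix"`` for GEO series-matrix text (only the block
        between ``!series_matrix_table_begin`` and
        ``!series_matrix_table_end`` is parsed), ``"delimited"`` for a
        plain table with a header row of sample ids and a first column of
        probe ids (separator chosen from the extension: ``.csv`` comma,
        otherwise tab).  ``None`` auto-detects: files whose first
        non-blank line starts with ``!`` are treated as series-matrix.
    """
    path = Path(path)
    text = path.read_text()
    if format is None:
        first = next((ln for ln in text.splitlines() if ln.strip()), "")
        format = "series_matrix" if first.startswith("!") else "delimited"
    if format == "delimited":
        return _parse_table(text, _sep_for(path))
    if format == "series_matrix":
        lines = text.splitlines()
        try:
            start = next(i for i, ln in enumerate(lines)
                         if ln.strip().lower().startswith("!series_matrix_table_begin"))
            end = next(i for i, ln in enumerate(lines)
                       if ln.strip().lower().startswith("!series_matrix_table_end"))
        except StopIteration:
            raise FormatError("series-matrix table delimiters not found") from None
        if end <= start + 1:
            raise FormatError("empty series-matrix table block")
        block = "\n".join(lines[start + 1:end])
        m = _parse_table(block, "\t")
        return m
    raise ConfigurationError(f"unknown beta-matrix format {format!r}")


def read_labels(path) -> dict:
    """Read a two-column sample/group table; group values must be
    ``case`` or ``control``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("label table needs at least two columns (sample, group)")
    out = {}
    for s, g in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if g not in GROUP_LABELS:
            raise ValidationError(f"group for sample {s!r} must be in {GROUP_LABELS}, got {g!r}")
        if s in out:
            raise ValidationError(f"duplicate sample id in label table: {s!r}")
        out[s] = g
    return out


def read_annotation(path, gene_column: str = "UCSC_RefGene_Name",
                    probe_column: str | None = None) -> AnnotationMap:
    """Read a manifest-style table into an :class:`AnnotationMap`.

    Gene cells are ``;``-separated symbol lists; symbols are deduplicated
    per probe and blank cells map to the empty set.  Section header lines
    starting with ``[`` (as found in raw Illumina manifests) are skipped.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("[")]
    df = pd.read_csv(io.StringIO("".join(lines)), sep=_sep_for(path),
                     dtype=str, keep_default_na=False)
    if gene_column not in df.columns:
        raise ConfigurationError(
            f"gene column {gene_column!r} not in table (columns: {list(df.columns)[:8]}...)"
        )
    if probe_column is None:
        for cand in ("IlmnID", "Name", "probe_id"):
            if cand in df.columns:
                probe_column = cand
                break
        else:
            probe_column = df.columns[0]
    elif probe_column not in df.columns:
        raise ConfigurationError(f"probe column {probe_column!r} not in table")
    entries: dict = {}
    for probe, cell in zip(df[probe_column], df[gene_column]):
        genes = {g.strip() for g in str(cell).split(";") if g.strip()}
        entries[str(probe)] = entries.get(str(probe), set()) | genes
    return AnnotationMap(entries)


def write_matrix(m, path, index_label: str = "ID_REF") -> None:
    """Write a matrix container (probe- or gene-level) as a TSV/CSV table.

    Values are written with Python's shortest round-trip float repr, so a
    write/read cycle preserves them bit-exactly.
    """
    path = Path(path)
    df = m.to_frame()
    df.to_csv(path, sep=_sep_for(path), index_label=index_label)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir,
                  summary: Mapping | None = None) -> dict:
    """Write named result tables as TSV plus an optional JSON run summary.

    Column order is taken from each table as given (deterministic);
    returns a manifest mapping table name to the written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        manifest[name] = str(p)
    if summary is not None:
        p = out_dir / "run_summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        manifest["run_summary"] = str(p)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
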