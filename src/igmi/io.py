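"""Tabular dataset and annotation I/O.

The dataset manifest is a TSV with columns ``wt_pdb``, ``mut_pdb``,
``mutations`` (';'-separated mutation codes) and ``ddg`` (kcal/mol); paths
are resolved relative to the manifest's directory.  Annotation tables for
fold construction are two-column TSVs (``sample_id, complex_id``,
``complex_id, domain_id`` or ``sample_id, partner_id``); identifiers are
opaque strings.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .splits import FoldAssignment
from .structure import (ComplexStructure, SampleRecord, parse_mutation_code,
                        parse_pdb, write_pdb)

__all__ = ["read_manifest", "write_manifest", "read_pdb_file",
           "write_pdb_file", "read_annotation_table", "write_fold_table"]


def read_pdb_file(path: str | Path) -> ComplexStructure:
    return parse_pdb(Path(path).read_text())


def write_pdb_file(structure: ComplexStructure, path: str | Path) -> None:
    Path(path).write_text(write_pdb(structure))


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Load samples from a manifest TSV (see module docstring)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"wt_pdb", "mut_pdb", "mutations", "ddg"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = path.parent
    samples = []
    for row in df.itertuples(index=False):
        muts = [parse_mutation_code(c) for c in str(row.mutations).split(";")]
        samples.append(SampleRecord(
            wt=read_pdb_file(base / row.wt_pdb),
            mut=read_pdb_file(base / row.mut_pdb),
            mutations=muts,
            ddg=float(row.ddg),
        ))
    return samples


def write_manifest(samples: list[SampleRecord], out_dir: str | Path,
                   prefix: str = "sample") -> Path:
    """Write per-sample PDB files plus the manifest TSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        wt_name = f"{prefix}{i:04d}_wt.pdb"
        mut_name = f"{prefix}{i:04d}_mut.pdb"
        write_pdb_file(s.wt, out_dir / wt_name)
        write_pdb_file(s.mut, out_dir / mut_name)
        rows.append({"wt_pdb": wt_name, "mut_pdb": mut_name,
                     "mutations": ";".join(m.code for m in s.mutations),
                     "ddg": s.ddg})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_annotation_table(path: str | Path,
                          multi: bool = True) -> dict[str, set[str] | str]:
    """Two-column TSV → mapping; ``multi`` collects values into sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation table needs two columns")
    key, val = df.columns[:2]
    if multi:
        out: dict[str, set[str]] = {}
        for k, v in zip(df[key], df[val]):
            out.setdefault(str(k), set()).add(str(v))
        return out
    return {str(k): str(v) for k, v in zip(df[key], df[val])}


def write_fold_table(assignment: FoldAssignment, out_dir: str | Path,
                     stem: str = "folds") -> tuple[Path, Path]:
    """Write the fold table (TSV) and the JSON certificate."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}.tsv"
    pd.DataFrame(
        [{"sample_id": sid, "fold": fold}
         for sid, fold in sorted(assignment.fold_of.items())]
    ).to_csv(tsv, sep="\t", index=False)
    cert = out_dir / f"{stem}_certificate.json"
    cert.write_text(json.dumps(assignment.certificate, indent=2))
    return tsv, cert
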