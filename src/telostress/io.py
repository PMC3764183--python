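"""Readers and writers for the plain-text study formats.

Expression matrix and detection calls are TSV with gene IDs in the first
column and sample IDs in the header; groups are two-column TSV
(sample, condition); gene sets are one-ID-per-line or GMT; networks are
two-column edge lists with '#' comments; screen tables are TSV
(mutant, initial_bp, final_bp[, delta_bp]); lane profiles are two-column
CSV (position, intensity) with marker metadata in a key-value sidecar;
ChIP tables are TSV quadruples. Output tables carry '#' provenance
comments (stage, parameters, seed).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .chip_quant import ChipMeasurement
from .expression_de import ExpressionBundle
from .responsiveness_screen import ScreenTable
from .telquant import LaneProfile

__all__ = [
    "read_expression_bundle",
    "write_expression_bundle",
    "read_gene_set",
    "write_gene_set",
    "write_gmt",
    "read_gmt",
    "write_edge_list",
    "read_screen_table",
    "write_screen_table",
    "read_lane_profile",
    "write_lane_profile",
    "read_chip_table",
    "write_chip_table",
    "write_key_value",
    "read_key_value",
    "provenance_header",
]


def provenance_header(stage: str, seed=None, **params) -> str:
    items = dict(params)
    if seed is not None:
        items["seed"] = seed
    lines = [f"# stage: {stage}"]
    lines += [f"# {k}: {v}" for k, v in items.items()]
    return "\n".join(lines) + "\n"


def _write_with_header(path, header: str, write_body) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        write_body(fh)


def read_expression_bundle(matrix_path, calls_path, groups_path) -> ExpressionBundle:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    calls = pd.read_csv(calls_path, sep="\t", index_col=0, comment="#", dtype=str)
    groups_df = pd.read_csv(groups_path, sep="\t", comment="#")
    groups = pd.Series(
        groups_df.iloc[:, 1].values, index=groups_df.iloc[:, 0].values, name="condition"
    )
    return ExpressionBundle(matrix=matrix, calls=calls, groups=groups)


def write_expression_bundle(bundle: ExpressionBundle, out_dir, prefix: str = "expression") -> dict:
    paths = {
        "matrix": os.path.join(out_dir, f"{prefix}_matrix.tsv"),
        "calls": os.path.join(out_dir, f"{prefix}_calls.tsv"),
        "groups": os.path.join(out_dir, f"{prefix}_groups.tsv"),
    }
    bundle.matrix.to_csv(paths["matrix"], sep="\t", index_label="gene", float_format="%.6f")
    bundle.calls.to_csv(paths["calls"], sep="\t", index_label="gene")
    bundle.groups.rename_axis("sample").to_frame().to_csv(paths["groups"], sep="\t")
    return paths


def read_gene_set(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_gene_set(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def write_gmt(sets: dict, path, description: str = "") -> None:
    """Write gene sets in GMT: name <tab> description <tab> member..."""
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = set(p for p in parts[2:] if p)
    return out


def write_edge_list(graph, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_screen_table(path, stress: str | None = None) -> ScreenTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    mutant = df[cols["mutant"]]
    initial = df[cols.get("initial_bp", cols.get("initial"))].astype(float)
    final = df[cols.get("final_bp", cols.get("final"))].astype(float)
    delta_col = cols.get("delta_bp", cols.get("delta"))
    table = ScreenTable.from_columns(mutant, initial, final, stress=stress or "")
    if delta_col is not None:
        supplied = df[delta_col].astype(float).to_numpy()
        if np.any(np.abs(supplied - table.table["delta"].to_numpy()) > 1.0):
            raise ValueError(
                f"{path}: supplied delta disagrees with final - initial by > 1 bp"
            )
    return table


def write_screen_table(screen: ScreenTable, path, header: str = "") -> None:
    def body(fh):
        out = screen.table.rename(
            columns={"initial": "initial_bp", "final": "final_bp", "delta": "delta_bp"}
        )
        out.to_csv(fh, sep="\t", index=False, float_format="%.3f")

    _write_with_header(path, header, body)


def read_lane_profile(profile_path, markers_path) -> LaneProfile:
    df = pd.read_csv(profile_path, comment="#")
    meta = read_key_value(markers_path)
    return LaneProfile(
        positions=df.iloc[:, 0].to_numpy(float),
        intensities=df.iloc[:, 1].to_numpy(float),
        marker_positions=(float(meta["marker1_pos"]), float(meta["marker2_pos"])),
        marker_sizes=(float(meta["marker1_size"]), float(meta["marker2_size"])),
    )


def write_lane_profile(profile: LaneProfile, profile_path, markers_path) -> None:
    pd.DataFrame(
        {"position": profile.positions, "intensity": profile.intensities}
    ).to_csv(profile_path, index=False, float_format="%.6f")
    write_key_value(
        {
            "marker1_pos": profile.marker_positions[0],
            "marker1_size": profile.marker_sizes[0],
            "marker2_pos": profile.marker_positions[1],
            "marker2_size": profile.marker_sizes[1],
        },
        markers_path,
    )


def read_chip_table(path) -> list[ChipMeasurement]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ChipMeasurement(
            tel_ip=float(r.tel_ip),
            aro_ip=float(r.aro_ip),
            tel_input=float(r.tel_input),
            aro_input=float(r.aro_input),
            condition=str(r.condition),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_chip_table(measurements, path, header: str = "") -> None:
    def body(fh):
        pd.DataFrame(
            [
                {
                    "condition": m.condition,
                    "replicate": m.replicate,
                    "tel_ip": m.tel_ip,
                    "aro_ip": m.aro_ip,
                    "tel_input": m.tel_input,
                    "aro_input": m.aro_input,
                }
                for m in measurements
            ]
        ).to_csv(fh, sep="\t", index=False, float_format="%.6f")

    _write_with_header(path, header, body)


def write_key_value(mapping: dict, path) -> None:
    """Plain `key = value` text block; iterables become comma-joined lists."""
    with open(path, "w") as fh:
        for k, v in mapping.items():
            if isinstance(v, (set, frozenset)):
                v = ",".join(sorted(str(x) for x in v))
            elif isinstance(v, (list, tuple)):
                v = ",".join(str(x) for x in v)
            fh.write(f"{k} = {v}\n")


def read_key_value(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
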