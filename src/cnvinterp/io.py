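"""Readers and writers for the plain-text formats the pipeline touches.

BED (gray lists, genes), bedGraph (binned depth), TSV and VCF-like dialects
for CNV calls, TSV for probe intensities and trio genotypes, and the
panel matrix + manifest pair. Everything is 0-based half-open internally;
only the VCF-like call dialect converts to 1-based inclusive coordinates.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .core import CnvCall, GenomeLayout, Interval, ParseError, ValidationError
from .depth import ChromBins, DepthProfile, GriddedProfile

log = logging.getLogger(__name__)

CALL_COLUMNS = [
    "chrom", "start", "end", "type", "copy_number", "depth_estimate",
    "n_bins", "quality", "mosaic_flag", "purity", "gap_lengths", "genes",
    "population_frequency", "graylist_fraction", "het_count", "inheritance",
]


def _data_lines(path):
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield ln, line


def read_bed(path, layout: Optional[GenomeLayout] = None):
    """Read a BED file into a list of (Interval, name) pairs.

    Requires >=3 whitespace-delimited columns; the 4th column (when
    present) is the record name. Coordinates are validated, and against
    the layout when one is supplied.
    """
    records = []
    for ln, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{ln}: expected >=3 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{ln}: non-integer coordinates") from None
        iv = Interval(chrom, start, end)  # raises ValidationError if inverted
        if layout is not None:
            layout.validate_interval(iv)
        name = fields[3] if len(fields) > 3 else ""
        records.append((iv, name))
    return records


def write_bed(records, path):
    with open(path, "w") as fh:
        for iv, name in records:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name:
                cols.append(name)
            fh.write("\t".join(cols) + "\n")


def read_depth_bedgraph(path, layout: GenomeLayout, sample_id="sample",
                        sex="female") -> DepthProfile:
    """Read 4-column chrom/start/end/value binned depth.

    Bins are sorted per chromosome and must not overlap; values must be
    non-negative. An empty file yields an empty profile with a warning.
    """
    per_chrom: dict = {}
    n = 0
    for ln, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{ln}: expected 4 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise ParseError(f"{path}:{ln}: malformed coordinates/value") from None
        iv = Interval(chrom, start, end)
        layout.validate_interval(iv)
        if value < 0:
            raise ValidationError(f"{path}:{ln}: negative depth value {value}")
        per_chrom.setdefault(chrom, []).append((start, end, value))
        n += 1
    if n == 0:
        log.warning("empty depth file %s: returning empty profile", path)
    bins = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts, ends, values = (np.array(x) for x in zip(*rows))
        bins[chrom] = ChromBins(starts, ends, values)  # rejects overlaps
    return DepthProfile(layout, bins, sample_id=sample_id, sex=sex)


def write_depth_bedgraph(profile, path):
    with open(path, "w") as fh:
        for chrom in profile.chroms():
            cb = profile.bins[chrom]
            for s, e, v in zip(cb.starts, cb.ends, cb.values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _call_row(c: CnvCall) -> dict:
    return {
        "chrom": c.chrom, "start": c.start, "end": c.end, "type": c.type,
        "copy_number": c.copy_number,
        "depth_estimate": "" if c.depth_estimate is None else f"{c.depth_estimate:.4f}",
        "n_bins": c.n_bins,
        "quality": "" if c.quality is None else f"{c.quality:.4g}",
        "mosaic_flag": int(c.mosaic_flag),
        "purity": "" if c.purity is None else f"{c.purity:.4f}",
        "gap_lengths": ",".join(str(g) for g in c.gap_lengths),
        "genes": ",".join(c.genes),
        "population_frequency": ("" if c.population_frequency is None
                                 else f"{c.population_frequency:.6f}"),
        "graylist_fraction": ("" if c.graylist_fraction is None
                              else f"{c.graylist_fraction:.4f}"),
        "het_count": "" if c.het_count is None else c.het_count,
        "inheritance": c.inheritance or "",
    }


def write_calls(calls, path, fmt: str = "tsv"):
    """Write CNV calls as TSV (0-based half-open) or a VCF-like dialect
    (1-based inclusive POS/END, SVTYPE/END/CN info keys)."""
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("# CNV calls; coordinates are 0-based half-open\n")
            fh.write("\t".join(CALL_COLUMNS) + "\n")
            for c in calls:
                row = _call_row(c)
                fh.write("\t".join(str(row[k]) for k in CALL_COLUMNS) + "\n")
    elif fmt == "vcf-like":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCF-like-CNV\n")
            fh.write("##INFO=<ID=SVTYPE>,<ID=END>,<ID=CN>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for c in calls:
                alt = "<DUP>" if c.type == "GAIN" else "<DEL>"
                svtype = "DUP" if c.type == "GAIN" else "DEL"
                qual = "." if c.quality is None else f"{c.quality:.4g}"
                info = f"SVTYPE={svtype};END={c.end};CN={c.copy_number}"
                fh.write(f"{c.chrom}\t{c.start + 1}\t.\tN\t{alt}\t{qual}\t.\t{info}\n")
    else:
        raise ValueError(f"unknown call format {fmt!r}")


def read_calls(path) -> list:
    """Read the TSV call dialect written by write_calls."""
    calls = []
    header = None
    for ln, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            if fields[0] != "chrom":
                raise ParseError(f"{path}:{ln}: missing call header row")
            header = fields
            continue
        row = dict(zip(header, fields))

        def _opt(key, conv):
            v = row.get(key, "")
            return conv(v) if v != "" else None

        calls.append(CnvCall(
            interval=Interval(row["chrom"], int(row["start"]), int(row["end"])),
            type=row["type"],
            copy_number=int(row["copy_number"]),
            depth_estimate=_opt("depth_estimate", float),
            n_bins=int(row["n_bins"]),
            quality=_opt("quality", float),
            mosaic_flag=bool(int(row.get("mosaic_flag", "0") or 0)),
            purity=_opt("purity", float),
            gap_lengths=tuple(int(g) for g in row.get("gap_lengths", "").split(",") if g),
            genes=tuple(g for g in row.get("genes", "").split(",") if g),
            population_frequency=_opt("population_frequency", float),
            graylist_fraction=_opt("graylist_fraction", float),
            het_count=_opt("het_count", int),
            inheritance=row.get("inheritance") or None,
        ))
    if header is None:
        raise ParseError(f"{path}: empty call file (no header)")
    return calls


def read_probes(path) -> pd.DataFrame:
    """Read probe intensities: TSV with columns chrom, pos, logr."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"chrom", "pos", "logr"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: probe table missing columns {sorted(missing)}")
    return df


def write_probes(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_trio_table(path) -> pd.DataFrame:
    """Read trio genotypes: TSV with chrom, pos, gt_mother, gt_father,
    proband_obs (ALT-allele count of the proband observation)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"chrom", "pos", "gt_mother", "gt_father", "proband_obs"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: trio table missing columns {sorted(missing)}")
    return df


def write_trio_table(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def write_panel(panel, matrix_path, manifest_path):
    """Store a population panel as a grid-cell x sample matrix TSV plus a
    sample manifest (id, sex). Missing cells are written as NaN."""
    sample_ids = list(panel.profiles)
    rows = []
    first = panel.profiles[sample_ids[0]]
    for chrom in first.layout.names:
        if chrom not in first.values:
            continue
        starts, ends = first.cell_bounds(chrom)
        block = {"chrom": np.repeat(chrom, len(starts)), "start": starts, "end": ends}
        for sid in sample_ids:
            block[sid] = panel.profiles[sid].values[chrom]
        rows.append(pd.DataFrame(block))
    pd.concat(rows, ignore_index=True).to_csv(matrix_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": sample_ids, "sex": [panel.sexes[s] for s in sample_ids]}
    ).to_csv(manifest_path, sep="\t", index=False)


def read_panel(matrix_path, manifest_path, layout: GenomeLayout):
    """Load a panel written by write_panel."""
    from .annotate import PopulationPanel  # local import avoids a cycle

    mat = pd.read_csv(matrix_path, sep="\t")
    man = pd.read_csv(manifest_path, sep="\t")
    sample_ids = [str(s) for s in man["sample_id"]]
    sexes = dict(zip(sample_ids, man["sex"]))
    widths = (mat["end"] - mat["start"]).to_numpy()
    grid_width = int(widths.max())
    profiles = {}
    for sid in sample_ids:
        values = {}
        for chrom, grp in mat.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            values[str(chrom)] = grp[sid].to_numpy(dtype=float)
        profiles[sid] = GriddedProfile(layout, grid_width, values,
                                       sample_id=sid, sex=sexes[sid])
    return PopulationPanel(layout=layout, grid_width=grid_width,
                           profiles=profiles, sexes=sexes)
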