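"""Readers and writers for the package's text formats.

Concentration columns declare their unit (`conc_unit`: pM/nM/uM/mM/M) and
are converted to µM at parse time, so all in-memory objects are unit-free
µM.  Every writer's output is readable by the matching reader.

Formats: band-table CSV, saturation-curve TSV, Hill-points TSV, Hill-result
JSON, promoter FASTA, inverted-repeat TSV/BED6, kinetic-read CSV, and
model-spec JSON/YAML (``sites: [{id, kd_uM}], coupling: [{i, j, omega}]``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding_model import PromoterBindingModel, SiteModel
from .errors import ParseError
from .hill_analysis import (
    BandTable,
    HillPoint,
    HillResult,
    Lane,
    SaturationCurve,
    SaturationPoint,
)
from .ir_scanner import InvertedRepeatPair, PromoterSequence
from .reporter_assay import KineticPlateRead

__all__ = [
    "read_band_table", "write_band_table",
    "read_saturation_curve", "write_saturation_curve",
    "read_hill_points", "write_hill_points",
    "read_hill_result", "write_hill_result",
    "read_promoter_fasta", "write_promoter_fasta",
    "read_ir_pairs", "write_ir_pairs", "write_ir_bed", "read_ir_bed",
    "read_kinetic_reads", "write_kinetic_reads",
    "read_model_spec", "write_model_spec",
]

_TO_UM = {"pM": 1e-6, "nM": 1e-3, "uM": 1.0, "µM": 1.0, "mM": 1e3, "M": 1e6}


def _conc_to_um(value: float, unit: str, where: str) -> float:
    try:
        return float(value) * _TO_UM[unit]
    except KeyError:
        raise ParseError(f"{where}: unknown concentration unit {unit!r}") from None


def _read_csv(path, **kw) -> pd.DataFrame:
    # round_trip parsing: the default (fast) float parser can be off by one ulp,
    # which breaks write->read identity
    kw.setdefault("float_precision", "round_trip")
    try:
        return pd.read_csv(path, **kw)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc


def read_band_table(path) -> BandTable:
    """Band-table CSV: ``lane,replicate,conc,conc_unit,band_0,band_1,...``."""
    df = _read_csv(path)
    band_cols = sorted(
        (c for c in df.columns if c.startswith("band_")), key=lambda c: int(c.split("_")[1])
    )
    if not band_cols:
        raise ParseError(f"{path}: no band_k columns found")
    lanes = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        conc = _conc_to_um(row.conc, str(row.conc_unit), f"{path}:{row_no}")
        lanes.append(
            Lane(
                concentration=conc,
                intensities=tuple(float(getattr(row, c)) for c in band_cols),
                replicate_id=int(row.replicate),
            )
        )
    return BandTable(lanes=tuple(lanes))


def write_band_table(table: BandTable, path) -> None:
    rows = []
    for i, lane in enumerate(table.lanes, start=1):
        row = {"lane": i, "replicate": lane.replicate_id, "conc": lane.concentration,
               "conc_unit": "uM"}
        row.update({f"band_{k}": v for k, v in enumerate(lane.intensities)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_saturation_curve(path) -> SaturationCurve:
    df = _read_csv(path, sep="\t")
    points = tuple(
        SaturationPoint(
            concentration=float(r.conc_uM), y=float(r.Y),
            sem=float(r.sem), n_replicates=int(r.n_replicates),
        )
        for r in df.itertuples(index=False)
    )
    return SaturationCurve(points=points)


def write_saturation_curve(curve: SaturationCurve, path) -> None:
    pd.DataFrame(
        [
            {"conc_uM": p.concentration, "Y": p.y, "sem": p.sem, "n_replicates": p.n_replicates}
            for p in curve.points
        ]
    ).to_csv(path, sep="\t", index=False)


def read_hill_points(path) -> list[HillPoint]:
    df = _read_csv(path, sep="\t")
    return [HillPoint(float(r.log_conc), float(r.log_theta)) for r in df.itertuples(index=False)]


def write_hill_points(points: list[HillPoint], path) -> None:
    pd.DataFrame(
        [{"log_conc": p.log_conc, "log_theta": p.log_theta} for p in points]
    ).to_csv(path, sep="\t", index=False)


def read_hill_result(path) -> HillResult:
    with open(path) as fh:
        return HillResult(**json.load(fh))


def write_hill_result(result: HillResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(result), fh, indent=2)
        fh.write("\n")


def read_promoter_fasta(path) -> list[PromoterSequence]:
    """FASTA reader; an ``anchor=N`` token in the description sets the anchor."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        anchor = None
        for token in rec.description.split():
            if token.startswith("anchor="):
                anchor = int(token.split("=", 1)[1])
        out.append(PromoterSequence(id=rec.id, sequence=str(rec.seq), anchor=anchor))
    if not out:
        raise ParseError(f"{path}: no FASTA records")
    return out


def write_promoter_fasta(seqs: list[PromoterSequence], path) -> None:
    records = [
        SeqRecord(
            Seq(s.sequence), id=s.id,
            description=f"anchor={s.anchor}" if s.anchor is not None else "",
        )
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


_IR_COLS = ["seq_id", "left_start", "left_end", "right_start", "right_end",
            "spacer", "mismatches", "left_arm", "right_arm"]


def read_ir_pairs(path) -> list[InvertedRepeatPair]:
    df = _read_csv(path, sep="\t")
    return [
        InvertedRepeatPair(
            seq_id=str(r.seq_id),
            left_start=int(r.left_start), left_end=int(r.left_end),
            right_start=int(r.right_start), right_end=int(r.right_end),
            spacer=int(r.spacer), mismatches=int(r.mismatches),
            left_arm=str(r.left_arm), right_arm=str(r.right_arm),
        )
        for r in df.itertuples(index=False)
    ]


def write_ir_pairs(pairs: list[InvertedRepeatPair], path) -> None:
    pd.DataFrame(
        [{c: getattr(p, c) for c in _IR_COLS} for p in pairs], columns=_IR_COLS
    ).to_csv(path, sep="\t", index=False)


def write_ir_bed(pairs: list[InvertedRepeatPair], path) -> None:
    """BED6, one interval per arm (0-based half-open), pair id in name, mismatches in score."""
    lines = []
    for n, p in enumerate(pairs, start=1):
        for tag, start, end in (
            ("L", p.left_start, p.left_end), ("R", p.right_start, p.right_end)
        ):
            lines.append(
                f"{p.seq_id}\t{start - 1}\t{end}\tpair{n}/{tag}\t{p.mismatches}\t+"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ir_bed(path):
    """Parse the BED6 arm intervals back as (seq_id, start_1based, end, name, score) tuples."""
    out = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(f"{path}:{line_no}: expected 6 BED fields, got {len(fields)}")
        out.append((fields[0], int(fields[1]) + 1, int(fields[2]), fields[3], int(fields[4])))
    return out


def read_kinetic_reads(path) -> list[KineticPlateRead]:
    """Long-format kinetic CSV:
    ``well,construct,antitoxin,iptg,replicate,time_s,od420,od600_first``."""
    df = _read_csv(path)
    # empty condition labels come back as NaN; restore them as empty strings
    for col in ("construct", "antitoxin"):
        df[col] = df[col].fillna("")
    reads = []
    for (well, rep), grp in df.groupby(["well", "replicate"], sort=False):
        grp = grp.sort_values("time_s")
        first = grp.iloc[0]
        reads.append(
            KineticPlateRead(
                well_id=str(well),
                times=tuple(grp["time_s"].to_numpy(float) / 60.0),
                od420=tuple(grp["od420"].to_numpy(float)),
                od600_first=float(first["od600_first"]),
                construct=str(first["construct"]),
                antitoxin=str(first["antitoxin"]),
                iptg=bool(first["iptg"]),
                replicate_id=int(rep),
            )
        )
    return reads


def write_kinetic_reads(reads: list[KineticPlateRead], path) -> None:
    rows = []
    for r in reads:
        for t, a in zip(r.times, r.od420):
            rows.append(
                {"well": r.well_id, "construct": r.construct, "antitoxin": r.antitoxin,
                 "iptg": r.iptg, "replicate": r.replicate_id,
                 "time_s": t * 60.0, "od420": a, "od600_first": r.od600_first}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_model_spec(path) -> PromoterBindingModel:
    """Model spec (JSON or YAML): ``sites: [{id, kd_uM}], coupling: [{i, j, omega}]``."""
    path = Path(path)
    text = path.read_text()
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(data, dict) or "sites" not in data:
        raise ParseError(f"{path}: model spec must be a mapping with a 'sites' list")
    unknown = set(data) - {"sites", "coupling"}
    if unknown:
        raise ParseError(f"{path}: unknown keys {sorted(unknown)}")
    sites = tuple(SiteModel(site_id=str(s["id"]), kd=float(s["kd_uM"])) for s in data["sites"])
    coupling = {
        frozenset((str(c["i"]), str(c["j"]))): float(c["omega"])
        for c in data.get("coupling", [])
    }
    return PromoterBindingModel(sites=sites, coupling=coupling)


def write_model_spec(model: PromoterBindingModel, path) -> None:
    path = Path(path)
    data = {
        "sites": [{"id": s.site_id, "kd_uM": s.kd} for s in model.sites],
        "coupling": [
            {"i": a, "j": b, "omega": omega}
            for (a, b), omega in sorted((tuple(sorted(k)), v) for k, v in model.coupling.items())
        ],
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
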