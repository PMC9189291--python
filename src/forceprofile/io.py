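"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are TSV/CSV via pandas; sequences are FASTA via Biopython; gel
images are 16-bit grayscale TIFF/PNG via imageio.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constructs import ArrestPeptide, Construct, ConstructSpec, build_construct
from .densitometry import LaneProfile
from .profile import ForceProfile, Peak, ProfilePoint, assemble_profile
from .stability import StabilityRecord

__all__ = [
    "read_domain_fasta",
    "write_library_tsv",
    "read_library_tsv",
    "write_constructs_fasta",
    "write_lane_profile_csv",
    "read_lane_profile_csv",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_peaks_tsv",
    "write_stability_tsv",
    "read_stability_tsv",
    "write_fit_report_json",
    "write_gel_image",
    "read_gel_image",
    "read_lane_map_tsv",
]

LIBRARY_COLUMNS = [
    "name",
    "domain_length",
    "linker_length",
    "control_kind",
    "L",
    "distance_to_ptc",
    "arrested_length",
    "full_length",
]


def read_domain_fasta(path: str | Path) -> str:
    """Sequence of the first FASTA record, uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return str(records[0].seq).upper()


def write_library_tsv(specs: Sequence[ConstructSpec], path: str | Path) -> None:
    rows = []
    for spec in specs:
        c = build_construct(spec)
        rows.append(
            {
                "name": spec.name,
                "domain_length": spec.domain_length,
                "linker_length": spec.linker_length,
                "control_kind": spec.control_kind,
                "L": spec.L,
                "distance_to_ptc": spec.distance_to_ptc,
                "arrested_length": c.arrested_length,
                "full_length": c.full_length,
            }
        )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path, ap: ArrestPeptide | None = None) -> list[ConstructSpec]:
    df = pd.read_csv(path, sep="\t")
    ap = ap or ArrestPeptide()
    specs = []
    for row in df.itertuples(index=False):
        spec = ConstructSpec(
            name=str(row.name),
            domain_length=int(row.domain_length),
            linker_length=int(row.linker_length),
            ap=ap,
            control_kind=str(row.control_kind),
            c_tail_length=0 if row.control_kind == "arrest_control" else 23,
        )
        if spec.L != int(row.L):
            raise ValueError(
                f"inconsistent library row {row.name}: stated L={row.L}, "
                f"recomputed L={spec.L}"
            )
        specs.append(spec)
    return specs


def write_constructs_fasta(
    constructs: Iterable[Construct], path: str | Path
) -> None:
    """Arrested and full-length chains of each construct, two records apiece."""
    records = []
    for c in constructs:
        records.append(
            SeqRecord(Seq(c.arrested_sequence), id=f"{c.name}|arrested", description="")
        )
        records.append(
            SeqRecord(Seq(c.full_sequence), id=f"{c.name}|full", description="")
        )
    SeqIO.write(records, str(path), "fasta")


def write_lane_profile_csv(profile: LaneProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"position": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, index=False)


def read_lane_profile_csv(
    path: str | Path, construct_name: str = "", replicate_id: str = ""
) -> LaneProfile:
    df = pd.read_csv(path)
    return LaneProfile(
        positions=df["position"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        construct_name=construct_name,
        replicate_id=replicate_id,
    )


def write_profile_tsv(profile: ForceProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> ForceProfile:
    df = pd.read_csv(path, sep="\t")
    points = [
        ProfilePoint(
            L=int(r.L),
            f_fl_mean=float(r.f_fl_mean),
            se=None if pd.isna(r.se) else float(r.se),
            n=int(r.n),
        )
        for r in df.itertuples(index=False)
    ]
    return assemble_profile(points, metadata={"source": str(path)})


def write_peaks_tsv(peaks: Sequence[Peak], path: str | Path) -> None:
    rows = []
    for p in peaks:
        span = p.repeat_annotation
        rows.append(
            {
                "L": p.L,
                "f_fl": p.f_fl,
                "prominence": p.prominence,
                "n_full_repeats": span.n_full_repeats if span else pd.NA,
                "tail_length": span.tail_length if span else pd.NA,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_stability_tsv(records: Sequence[StabilityRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": [r.label for r in records],
            "n_repeats": [r.n_repeats for r in records],
            "dG_kcal_mol": [r.dG for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_stability_tsv(path: str | Path) -> list[StabilityRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        StabilityRecord(str(r.label), int(r.n_repeats), float(r.dG_kcal_mol))
        for r in df.itertuples(index=False)
    ]


def write_fit_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def write_gel_image(image: np.ndarray, path: str | Path) -> None:
    """16-bit grayscale TIFF or PNG, chosen by file extension."""
    iio.imwrite(str(path), np.asarray(image, dtype=np.uint16))


def read_gel_image(path: str | Path) -> np.ndarray:
    img = iio.imread(str(path))
    if img.ndim == 3:  # collapse any color channels
        img = img.mean(axis=-1)
    return np.asarray(img, dtype=float)


def read_lane_map_tsv(path: str | Path) -> pd.DataFrame:
    """Lane regions: columns lane, row_start, row_stop, col_start, col_stop."""
    df = pd.read_csv(path, sep="\t")
    required = {"lane", "row_start", "row_stop", "col_start", "col_stop"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lane map missing columns: {sorted(missing)}")
    return df
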