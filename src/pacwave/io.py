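"""Readers, writers and run configuration.

Formats: FASTA (70-column wrap) for genomes, FASTQ (Phred+33, constant
quality) for simulated reads, bedGraph (0-based half-open) for coverage
tracks, TSV for per-read/per-molecule tables, JSON for att-site coordinates
and analysis reports, YAML (flat mapping) for run configuration.  Every
writer here is matched by a reader so a run's outputs round-trip.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageProfile
from .genome import AttSite, ReplicatedGenome
from .simulate import PackagedMolecule, ReadPairSet, SimParams

_QUAL_CHAR = "I"  # constant Phred 40


def write_fasta(genomes, path) -> None:
    recs = [
        SeqRecord(Seq(g.sequence), id=g.name, description=f"topology={g.topology}")
        for g in ([genomes] if isinstance(genomes, ReplicatedGenome) else genomes)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(recs)


def read_fasta(path) -> list[ReplicatedGenome]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topo = "circular" if "topology=circular" in rec.description else (
            "linear" if "topology=linear" in rec.description else "circular")
        out.append(ReplicatedGenome(rec.id, str(rec.seq).upper(), topo))
    return out


def write_fastq_pair(readset: ReadPairSet, prefix) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``."""
    prefix = Path(prefix)
    paths = (prefix.parent / (prefix.name + "_R1.fastq"),
             prefix.parent / (prefix.name + "_R2.fastq"))
    for path, mates, tag in zip(paths, (readset.r1, readset.r2), ("/1", "/2")):
        with open(path, "w") as fh:
            for rid, seq in mates:
                fh.write(f"@{rid}{tag}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")
    return paths


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_att_json(att: AttSite, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(att), fh, indent=1)


def read_att_json(path) -> AttSite:
    with open(path) as fh:
        return AttSite(**json.load(fh))


def write_bedgraph(profile: CoverageProfile, path, track_name: str | None = None) -> None:
    """One bedGraph track per frame, 0-based half-open, 1 value per bin."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name or profile.frame}"\n')
        b = profile.bin_size
        for i, v in enumerate(profile.depth):
            end = min((i + 1) * b, profile.length)
            fh.write(f"{profile.frame}\t{i * b}\t{end}\t{v:.6g}\n")


def read_bedgraph(path) -> CoverageProfile:
    rows = []
    frame = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            f, s, e, v = line.split("\t")
            frame = f
            rows.append((int(s), int(e), float(v)))
    if not rows:
        raise ValueError(f"empty bedGraph {path}")
    bin_size = rows[0][1] - rows[0][0]
    length = rows[-1][1]
    depth = np.array([v for _, _, v in rows])
    return CoverageProfile(frame, bin_size, depth, length)


def write_molecule_table(molecules: list[PackagedMolecule], path) -> None:
    rows = [
        (m.molecule_id, m.series_id, m.headful_index, m.origin,
         f, s, e, st)
        for m in molecules
        for f, s, e, st in m.segments
    ]
    pd.DataFrame(rows, columns=[
        "molecule_id", "series_id", "headful_index", "origin",
        "frame", "start", "end", "strand",
    ]).to_csv(path, sep="\t", index=False)


def write_truth_table(readset: ReadPairSet, path) -> None:
    readset.truth.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


@dataclass
class RunConfig:
    """Resolved parameters of one simulate/analyze run.

    Flat key=value structure; round-trips losslessly through YAML.  CLI
    flags mirror these keys one-to-one and take precedence over the file.
    """

    # experiment geometry
    condition: str = "induction"
    host_length: int = 2_000_000
    host_gc: float = 0.635
    attB_pos: int = 1_200_000
    phage_length: int = 65_149
    phage_gc: float = 0.635
    attP_pos: int = 62_750
    orientation: str = "reverse"
    att_core: str = "TGGTGCGGACGGAGAGA"
    # packaging model
    redundancy: float = 0.10
    pac_pos: int = 23_500
    pac_jitter_sd: float = 2000.0
    mean_headfuls: float = 3.0
    f_int: float | None = None       # None -> condition preset
    bg_rate: float | None = None
    direction: str = "toward_attL"
    n_series: int = 6000
    # sequencing
    fragment_mean: float = 900.0
    fragment_sd: float = 100.0
    read_len: int = 250
    error_rate: float = 0.001
    pairs_per_kb: float = 0.05
    # classifier
    k: int = 31
    min_anchor: int = 20
    # analysis
    bin_size: int = 1000
    n_windows: int = 12
    threshold_mult: float = 2.0
    run_rule: int = 3
    span: int = 800_000
    seed: int = 0

    def sim_params(self) -> SimParams:
        from .simulate import CONDITION_PRESETS

        preset = CONDITION_PRESETS.get(self.condition, {})
        f_int = self.f_int if self.f_int is not None else preset.get("f_int", 0.018)
        bg = self.bg_rate if self.bg_rate is not None else preset.get("bg_rate", 0.022)
        return SimParams(
            phage_length=self.phage_length, redundancy=self.redundancy,
            pac_pos=self.pac_pos, pac_jitter_sd=self.pac_jitter_sd,
            mean_headfuls=self.mean_headfuls, f_int=f_int,
            direction=self.direction, bg_rate=bg,
            n_series=self.n_series, seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from a YAML mapping or a flat ``key=value`` file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):  # flat key=value lines
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = yaml.safe_load(val.strip())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)
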