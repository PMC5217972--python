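"""Simulator of pac-initiated processive headful packaging.

The mechanistic model: a terminase recognises a *pac* site on phage DNA and
makes a first, imprecisely positioned cut; successive capsids are then
filled with exactly one headful ``H = round(L_p * (1 + r))`` each (``r`` =
terminal redundancy), tiling the substrate processively with no gaps.  The
number of headfuls per initiation event is geometric with mean ``m``
(memoryless continuation after each completed capsid).

Three packaging substrates are modelled:

* *episomal* — an unbounded concatemer of the phage circle, yielding
  circularly permuted, terminally redundant phage genomes;
* *integrated* — a phage copy recombined into the host chromosome at the
  att site; the series runs from pac across the attL junction into one
  host flank and keeps walking the (circular) host, so headfuls 2, 3, ...
  contain pure host DNA;
* *background* — a single uniformly placed host fragment of one headful,
  the flat generalized-transduction floor.

Coordinates are 0-based half-open throughout; circular arithmetic is
modulo frame length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import AttSite, LysogenMap, ReplicatedGenome, build_lysogen, revcomp

PHAGE_LENGTH = 65_149          # assembled phage genome size, bp
DEFAULT_PAC = 23_500           # coverage maximum near the terminase genes
DEFAULT_ATTP = 62_750          # att core position in the phage frame
DEFAULT_REDUNDANCY = 0.10      # headful exceeds the genome by ~10%

#: Condition presets.  ``f_int`` (fraction of packaging series initiated on
#: an integrated phage copy) and ``bg_rate`` (fraction of series that are
#: plain generalized transduction) are calibrated from the closed-form
#: host-fraction expectation so the two presets reproduce the observed
#: ~2.2% (induction) and ~0.6% (infection) packaged-host-DNA fractions and
#: their near-att shares; see docs/methods.md for the derivation.
CONDITION_PRESETS = {
    "induction": {"f_int": 0.018, "bg_rate": 0.022},
    "infection": {"f_int": 0.0054, "bg_rate": 0.0049},
}


@dataclass
class SimParams:
    """Parameters of one simulated packaging experiment."""

    phage_length: int = PHAGE_LENGTH
    redundancy: float = DEFAULT_REDUNDANCY
    pac_pos: int = DEFAULT_PAC
    pac_jitter_sd: float = 2000.0
    mean_headfuls: float = 3.0
    f_int: float = 0.018
    direction: str = "toward_attL"
    bg_rate: float = 0.022
    n_series: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_headfuls < 1:
            raise ValueError("mean_headfuls must be >= 1")
        for name in ("redundancy", "f_int", "bg_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.direction not in ("toward_attL", "toward_attR"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.n_series < 1:
            raise ValueError("n_series must be >= 1")

    @property
    def headful(self) -> int:
        """Headful size H = round(L_p * (1 + r)), bp."""
        return int(round(self.phage_length * (1.0 + self.redundancy)))


@dataclass
class PackagedMolecule:
    """One virion's DNA as an interval walk plus source-frame truth.

    ``path_frame``/``path_start``/``path_length`` give the packaged interval
    in the substrate frame (lysogen, phage concatemer, or host), from which
    the molecule sequence is extracted.  ``segments`` is the same DNA
    expressed as (frame, start, end, strand) intervals in the *source*
    host/phage frames — the simulator's truth unit.
    """

    series_id: int
    headful_index: int
    origin: str  # integrated | episomal | background
    path_frame: str
    path_start: int
    path_length: int
    segments: list[tuple[str, int, int, str]] = field(default_factory=list)

    @property
    def molecule_id(self) -> str:
        return f"S{self.series_id:06d}.{self.headful_index}"

    @property
    def length(self) -> int:
        return self.path_length


def draw_series_length(m: float, rng: np.random.Generator) -> int:
    """Number of headfuls in one processive series: geometric, mean ``m``.

    P(k) = (1/m) * (1 - 1/m)**(k-1) on k = 1, 2, ...
    """
    if m < 1:
        raise ValueError("mean series length must be >= 1")
    if m == 1:
        return 1
    return int(rng.geometric(1.0 / m))


def _first_cut_jitter(sd: float, rng: np.random.Generator) -> int:
    """Cleavage-position jitter: Normal(0, sd) truncated at +/-3 sd."""
    if sd <= 0:
        return 0
    j = rng.normal(0.0, sd)
    return int(round(np.clip(j, -3 * sd, 3 * sd)))


def phage_distance_to_junction(
    att: AttSite, pac_pos: int, phage_length: int, direction: str
) -> int:
    """Distance d from the pac cut to the att junction along the packaging
    walk, in phage bases (the phage content of the first headful)."""
    Lp = phage_length
    c = att.core_len
    rev = att.orientation == "reverse"
    toward_L = direction == "toward_attL"
    if toward_L == rev:
        # walk reaches the junction moving up native phage coordinates
        return (att.attP_pos - pac_pos) % Lp
    return (pac_pos - att.attP_pos - c) % Lp


def _lysogen_intervals_to_segments(
    lys: LysogenMap, start: int, length: int
) -> list[tuple[str, int, int, str]]:
    """Express a circular lysogen interval as host/phage source segments."""
    L = lys.length
    segs: list[tuple[str, int, int, str]] = []
    start %= L
    # split circular interval into linear pieces
    pieces = []
    s, rem = start, length
    while rem > 0:
        take = min(rem, L - s)
        pieces.append((s, s + take))
        rem -= take
        s = 0
    bounds = sorted({lys.attL_pos, lys.attL_pos + lys.core_len,
                     lys.attR_pos + lys.core_len})
    for p0, p1 in pieces:
        cuts = [p0] + [b for b in bounds if p0 < b < p1] + [p1]
        for a, b in zip(cuts[:-1], cuts[1:]):
            f, s0 = lys.to_source(a)
            f1, s1 = lys.to_source(b - 1)
            assert f == f1, "piece crosses a frame boundary"
            if s1 >= s0:
                segs.append((f, s0, s1 + 1, "+"))
            else:  # reverse-orientation phage piece
                segs.append((f, s1, s0 + 1, "-"))
    return _merge_segments(segs)


def _merge_segments(segs):
    out = []
    for seg in segs:
        if out:
            f, s0, e0, st = out[-1]
            f1, s1, e1, st1 = seg
            if f == f1 and st == st1 == "+" and s1 == e0:
                out[-1] = (f, s0, e1, st)
                continue
            if f == f1 and st == st1 == "-" and e1 == s0:
                out[-1] = (f, s1, e0, st)
                continue
        out.append(seg)
    return out


def _circular_frame_segments(frame: str, L: int, start: int, length: int,
                             strand: str = "+") -> list[tuple[str, int, int, str]]:
    segs = []
    s, rem = start % L, length
    while rem > 0:
        take = min(rem, L - s)
        segs.append((frame, s, s + take, strand))
        rem -= take
        s = 0
    return segs


def generate_series(
    params: SimParams,
    origin: str,
    lysogen: LysogenMap | None,
    rng: np.random.Generator,
    series_id: int = 0,
    n_headfuls: int | None = None,
    att: AttSite | None = None,
) -> list[PackagedMolecule]:
    """One processive packaging series: k headfuls tiling the substrate.

    Integrated series walk the lysogen from the jittered pac cut toward the
    att junction designated by ``params.direction`` and on into the circular
    host; episomal series walk an unbounded phage concatemer.
    """
    H = params.headful
    k = n_headfuls if n_headfuls is not None else draw_series_length(
        params.mean_headfuls, rng)
    jit = _first_cut_jitter(params.pac_jitter_sd, rng)
    mols: list[PackagedMolecule] = []
    if origin == "episomal":
        Lp = params.phage_length
        # packaging walks up native phage coordinates when orientation is
        # reverse (the same physical direction as the integrated walk)
        s0 = (params.pac_pos + jit) % Lp
        for i in range(1, k + 1):
            start = (s0 + (i - 1) * H) % Lp
            mols.append(PackagedMolecule(
                series_id, i, "episomal", "phage", start, H,
                _circular_frame_segments("phage", Lp, start, H)))
        return mols
    if origin == "integrated":
        if lysogen is None or att is None:
            raise ValueError("integrated series require a lysogen and att site")
        d = phage_distance_to_junction(
            att, params.pac_pos, params.phage_length, params.direction)
        c = lysogen.core_len
        L = lysogen.length
        if params.direction == "toward_attL":
            # cut sits d phage-bases to the right of the attL core end;
            # the walk proceeds leftward (decreasing lysogen coordinate)
            cut = lysogen.attL_pos + c + d + jit
            for i in range(1, k + 1):
                start = (cut - i * H) % L
                mols.append(PackagedMolecule(
                    series_id, i, "integrated", "lysogen", start, H,
                    _lysogen_intervals_to_segments(lysogen, start, H)))
        else:
            cut = lysogen.attR_pos - d - jit
            for i in range(1, k + 1):
                start = (cut + (i - 1) * H) % L
                mols.append(PackagedMolecule(
                    series_id, i, "integrated", "lysogen", start, H,
                    _lysogen_intervals_to_segments(lysogen, start, H)))
        return mols
    raise ValueError(f"unknown origin {origin!r}")


def _background_molecule(params: SimParams, host_length: int,
                         rng: np.random.Generator, series_id: int) -> PackagedMolecule:
    H = params.headful
    start = int(rng.integers(0, host_length))
    return PackagedMolecule(
        series_id, 1, "background", "host", start, H,
        _circular_frame_segments("host", host_length, start, H))


def simulate_experiment(
    params: SimParams,
    host: ReplicatedGenome,
    phage: ReplicatedGenome,
    att: AttSite,
    rng: np.random.Generator | None = None,
) -> tuple[list[PackagedMolecule], LysogenMap, dict]:
    """Run ``n_series`` packaging events and return molecules + truth summary.

    Each series is background with probability ``bg_rate``; otherwise it is
    integrated with probability ``f_int``, else episomal.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lysogen = build_lysogen(host, phage, att)
    molecules: list[PackagedMolecule] = []
    n_by_origin = {"integrated": 0, "episomal": 0, "background": 0}
    for sid in range(params.n_series):
        u = rng.random()
        if u < params.bg_rate:
            molecules.append(_background_molecule(params, host.length, rng, sid))
            n_by_origin["background"] += 1
        elif rng.random() < params.f_int:
            molecules.extend(generate_series(
                params, "integrated", lysogen, rng, sid, att=att))
            n_by_origin["integrated"] += 1
        else:
            molecules.extend(generate_series(
                params, "episomal", lysogen, rng, sid, att=att))
            n_by_origin["episomal"] += 1
    host_bases = phage_bases = 0
    for m in molecules:
        for f, s, e, _ in m.segments:
            if f == "host":
                host_bases += e - s
            else:
                phage_bases += e - s
    total = host_bases + phage_bases
    summary = {
        "n_series": params.n_series,
        "n_molecules": len(molecules),
        "series_by_origin": n_by_origin,
        "headful": params.headful,
        "pac_to_junction_bp": phage_distance_to_junction(
            att, params.pac_pos, params.phage_length, params.direction),
        "phage_bases": phage_bases,
        "host_bases": host_bases,
        "host_base_fraction": host_bases / total if total else 0.0,
    }
    return molecules, lysogen, summary


def expected_host_fraction(params: SimParams, att: AttSite) -> float:
    """Closed-form expectation of the packaged host-base fraction.

    Background series contribute H host bases; integrated series of mean
    length m contribute m*H - d host bases; episomal series none.
    """
    H = params.headful
    d = phage_distance_to_junction(
        att, params.pac_pos, params.phage_length, params.direction)
    m, b, f = params.mean_headfuls, params.bg_rate, params.f_int
    host = b * H + (1 - b) * f * (m * H - d)
    total = b * H + (1 - b) * m * H
    return host / total


# ---------------------------------------------------------------------------
# read generation


@dataclass
class ReadPairSet:
    """Paired-end reads plus per-mate source truth.

    ``truth`` has one row per (read, mate, source segment):
    read_id, mate, molecule_id, origin, frame, start, end, strand.
    """

    r1: list[tuple[str, str]]  # (read_id, sequence)
    r2: list[tuple[str, str]]
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.r1)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _path_interval_to_segments(mol: PackagedMolecule, frames: dict,
                               lysogen: LysogenMap | None,
                               off: int, length: int):
    """Truth segments for a sub-interval of a molecule's packaged path."""
    start = mol.path_start + off
    if mol.path_frame == "lysogen":
        return _lysogen_intervals_to_segments(lysogen, start, length)
    L = len(frames[mol.path_frame].sequence)
    return _circular_frame_segments(mol.path_frame, L, start, length)


def molecules_to_reads(
    molecules: Iterable[PackagedMolecule],
    frames: dict,
    lysogen: LysogenMap | None = None,
    fragment_mean: float = 900.0,
    fragment_sd: float = 100.0,
    read_len: int = 250,
    error_rate: float = 0.001,
    pairs_per_kb: float = 1.0,
    rng: np.random.Generator | None = None,
) -> ReadPairSet:
    """Shear molecules into fragments and sequence both ends.

    Fragment count per molecule is Poisson(pairs_per_kb * length/1000);
    fragment starts are uniform along the molecule and lengths
    Normal(fragment_mean, fragment_sd) truncated to [read_len, molecule
    length].  Mates are the two fragment ends, the right mate
    reverse-complemented; substitution errors are applied at ``error_rate``.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    if read_len > fragment_mean:
        raise ValueError("read_len must not exceed fragment_mean")
    if error_rate < 0 or pairs_per_kb < 0:
        raise ValueError("rates must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(0)
    lys_genome = (ReplicatedGenome("lysogen", lysogen.sequence, "circular")
                  if lysogen is not None else None)
    r1, r2, truth_rows = [], [], []
    for mol in molecules:
        n_frag = int(rng.poisson(pairs_per_kb * mol.length / 1000.0))
        if n_frag == 0:
            continue
        src = lys_genome if mol.path_frame == "lysogen" else frames[mol.path_frame]
        mseq = src.fetch(mol.path_start, mol.path_length)
        for fi in range(n_frag):
            fl = int(round(rng.normal(fragment_mean, fragment_sd)))
            fl = max(read_len, min(fl, mol.length))
            fstart = int(rng.integers(0, mol.length - fl + 1))
            frag = mseq[fstart:fstart + fl]
            rid = f"{mol.molecule_id}.F{fi}"
            left = frag[:read_len]
            right = revcomp(frag[-read_len:])
            r1.append((rid, _add_errors(left, error_rate, rng)))
            r2.append((rid, _add_errors(right, error_rate, rng)))
            for mate, (o, ln, st) in enumerate(
                [(fstart, read_len, "+"), (fstart + fl - read_len, read_len, "-")],
                start=1,
            ):
                for f, s, e, seg_st in _path_interval_to_segments(
                        mol, frames, lysogen, o, ln):
                    # mate strand composes with the path-segment strand
                    flip = (st == "-") != (seg_st == "-")
                    truth_rows.append((rid, mate, mol.molecule_id, mol.origin,
                                       f, s, e, "-" if flip else "+"))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "mate", "molecule_id", "origin",
                 "frame", "start", "end", "strand"],
    )
    return ReadPairSet(r1=r1, r2=r2, truth=truth)
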