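"""Coordinate frames of a temperate-phage / host system sharing an att core.

Three frames matter: the circular *host* chromosome carrying a single
``attB`` core, the circular *phage* genome carrying the identical ``attP``
core, and the *lysogen* formed by Campbell-type crossover within the shared
core.  Integration duplicates the core into the two junctions ``attL`` and
``attR``; every lysogen position outside the cores maps back to exactly one
source position.

All coordinates are 0-based, half-open; circular positions are reduced
modulo the frame length.  Conversion to 1-based conventions happens only at
I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: The 17-bp recombination core shared by host (attB) and phage (attP).
DEFAULT_ATT_CORE = "TGGTGCGGACGGAGAGA"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReplicatedGenome:
    """A named DNA molecule with explicit topology."""

    name: str
    sequence: str
    topology: str = "circular"  # or "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not self.sequence:
            raise ValueError("empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, length: int) -> str:
        """Substring of given length starting at ``start`` (circular wrap)."""
        L = self.length
        if length < 0:
            raise ValueError("negative length")
        if self.topology == "linear":
            if start < 0 or start + length > L:
                raise IndexError("interval outside linear genome")
            return self.sequence[start : start + length]
        start %= L
        if start + length <= L:
            return self.sequence[start : start + length]
        reps = self.sequence[start:]
        need = length - len(reps)
        whole, rem = divmod(need, L)
        return reps + self.sequence * whole + self.sequence[:rem]


@dataclass(frozen=True)
class AttSite:
    """The shared recombination core and its location in both frames.

    ``orientation`` records the sense of the phage relative to the host at
    integration: ``reverse`` means the phage is reverse-complemented before
    Campbell crossover (a single flag, sufficient for junction geometry).
    """

    core: str
    attB_pos: int
    attP_pos: int
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if len(self.core) < 8:
            raise ValueError("att core must be at least 8 bp")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def core_len(self) -> int:
        return len(self.core)

    def validate(self, host: ReplicatedGenome, phage: ReplicatedGenome) -> None:
        """Check the core occurs exactly once in each frame at the stated spot."""
        if host.sequence.count(self.core) != 1:
            raise ValueError("att core must occur exactly once in host")
        if host.sequence.index(self.core) != self.attB_pos:
            raise ValueError("attB_pos does not match host core location")
        pseq = phage.sequence if self.orientation == "forward" else revcomp(phage.sequence)
        ppos = self.attP_pos if self.orientation == "forward" else (
            phage.length - self.attP_pos - self.core_len
        )
        if pseq.count(self.core) != 1:
            raise ValueError("att core must occur exactly once in phage (per orientation)")
        if pseq.index(self.core) != ppos:
            raise ValueError("attP_pos does not match phage core location")


@dataclass(frozen=True)
class LysogenMap:
    """The integrated lysogen and the correspondence back to source frames.

    ``attL_pos``/``attR_pos`` are the 0-based starts of the two core copies
    in the lysogen frame.  ``to_source`` is total: the attL core is
    attributed to the host frame and the attR core to the phage frame (the
    core is identical everywhere, so the attribution is a convention); it is
    invertible on all non-core positions.
    """

    sequence: str
    attL_pos: int
    attR_pos: int
    host_length: int
    phage_length: int
    core_len: int
    orientation: str
    attP_native: int = 0
    host_name: str = "host"
    phage_name: str = "phage"
    topology: str = "circular"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def _phage_source(self, q: int) -> int:
        """Map a position of the (possibly reverse-complemented) inserted phage
        back to native phage coordinates."""
        if self.orientation == "forward":
            return q
        return self.phage_length - 1 - q

    def to_source(self, pos: int) -> tuple[str, int]:
        """Map a lysogen position to ``(frame, source position)``."""
        pos %= self.length
        aL, aR, c = self.attL_pos, self.attR_pos, self.core_len
        if pos < aL:
            return "host", pos
        if pos < aL + c:  # attL core -> host attB core
            return "host", pos
        if pos < aR + c:  # prophage body plus attR core -> phage attP core
            q = (self._attP_inserted() + (pos - aL)) % self.phage_length
            return "phage", self._phage_source(q)
        return "host", pos - self.phage_length

    def _attP_inserted(self) -> int:
        if self.orientation == "forward":
            return self.attP_native
        return self.phage_length - self.attP_native - self.core_len

    def from_source(self, frame: str, pos: int) -> int:
        """Inverse of :meth:`to_source` (non-core positions; cores map to
        their attributed copy)."""
        c = self.core_len
        if frame == "host":
            pos %= self.host_length
            if pos < self.attL_pos + c:
                return pos
            return pos + self.phage_length
        if frame == "phage":
            pos %= self.phage_length
            q = pos if self.orientation == "forward" else self.phage_length - 1 - pos
            attP_ins = self._attP_inserted()
            off = (q - attP_ins) % self.phage_length
            if off < c:  # phage core is attributed to the attR copy
                off += self.phage_length
            return self.attL_pos + off
        raise ValueError(f"unknown frame {frame!r}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_genome(
    length: int,
    gc: float = 0.5,
    seed=0,
    name: str = "genome",
    topology: str = "circular",
) -> ReplicatedGenome:
    """Draw an i.i.d. random genome with expected GC fraction ``gc``."""
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)
    return ReplicatedGenome(name=name, sequence=bases.tobytes().decode(), topology=topology)


def plant_att_core(genome: ReplicatedGenome, core: str, pos: int) -> ReplicatedGenome:
    """Overwrite ``genome`` at ``pos`` with the att core.

    Fails if the core already occurs elsewhere (the downstream junction
    logic requires a unique core per frame).
    """
    if pos < 0 or pos + len(core) > genome.length:
        raise ValueError("core does not fit at pos")
    seq = genome.sequence[:pos] + core + genome.sequence[pos + len(core):]
    n = seq.count(core)
    if n != 1:
        raise ValueError(
            f"att core occurs {n} times after planting; genome must be core-free elsewhere"
        )
    return replace(genome, sequence=seq)


def build_lysogen(
    host: ReplicatedGenome, phage: ReplicatedGenome, att: AttSite
) -> LysogenMap:
    """Campbell-type integration of the phage circle into the host at attB.

    The crossover happens within the shared core, which therefore appears
    twice in the product, at attL (host-left | core | phage) and attR
    (phage | core | host-right).  Lysogen length is exactly the sum of the
    two genome lengths.
    """
    att.validate(host, phage)
    c = att.core_len
    if att.orientation == "forward":
        pseq = phage.sequence
        attP = att.attP_pos
    else:
        pseq = revcomp(phage.sequence)
        attP = phage.length - att.attP_pos - c
    Lp = phage.length
    attB = att.attB_pos
    # phage circle opened just downstream of its core
    rot = pseq[attP + c:] + pseq[:attP]
    lys_seq = (
        host.sequence[:attB] + att.core + rot + att.core + host.sequence[attB + c:]
    )
    lys = LysogenMap(
        sequence=lys_seq,
        attL_pos=attB,
        attR_pos=attB + Lp,
        host_length=host.length,
        phage_length=Lp,
        core_len=c,
        orientation=att.orientation,
        attP_native=att.attP_pos,
        host_name=host.name,
        phage_name=phage.name,
        topology=host.topology,
    )
    if len(lys_seq) != host.length + phage.length:
        raise AssertionError("lysogen length mismatch")
    return lys


def excise(lysogen: LysogenMap, att: AttSite) -> tuple[ReplicatedGenome, ReplicatedGenome]:
    """In-silico excision: crossover of attL x attR, inverse of integration.

    Returns the original host and phage sequences exactly.
    """
    c = lysogen.core_len
    aL, aR = lysogen.attL_pos, lysogen.attR_pos
    host_seq = lysogen.sequence[:aL] + att.core + lysogen.sequence[aR + c:]
    rot = lysogen.sequence[aL + c: aR]
    # rot covers inserted-phage positions attP+c .. Lp-1 then 0 .. attP-1
    Lp = lysogen.phage_length
    attP = att.attP_pos if lysogen.orientation == "forward" else Lp - att.attP_pos - c
    tail = Lp - attP - c  # bases of rot preceding position 0
    pseq = rot[tail:] + att.core + rot[:tail]
    if lysogen.orientation == "reverse":
        pseq = revcomp(pseq)
    return (
        ReplicatedGenome(lysogen.host_name, host_seq, "circular"),
        ReplicatedGenome(lysogen.phage_name, pseq, "circular"),
    )
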