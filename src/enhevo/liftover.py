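"""UCSC chain files and chain-based interval lift-over.

A chain records a scored pairwise alignment between a *source* genome (the
``t`` fields of the chain header, the coordinate system intervals are lifted
from) and a *target* genome (the ``q`` fields). Alignment blocks are
``(size, dt, dq)`` triples: ``size`` aligned bases followed by gaps of
``dt`` source bases and ``dq`` target bases; the last block carries no
trailing gaps.

``map_interval`` mirrors single-chain liftOver semantics: the highest-score
chain overlapping the interval is chosen, the fraction of interval bases in
aligned blocks must reach ``min_match`` (default 0.95, the liftOver
default), and the lifted interval spans from the first to the last mapped
base in target coordinates. Negative-strand target coordinates are
normalized to the plus strand on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval

__all__ = [
    "Chain",
    "ChainSet",
    "MappingResult",
    "ChainParseError",
    "parse_chain",
    "write_chain",
    "map_interval",
]


class ChainParseError(ValueError):
    pass


@dataclass
class Chain:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str = "1"
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.blocks:
            raise ChainParseError(f"chain {self.chain_id}: no alignment blocks")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ChainParseError(
                f"chain {self.chain_id}: last block must have no trailing gaps"
            )
        if any(size < 1 for size, _, _ in self.blocks):
            raise ChainParseError(f"chain {self.chain_id}: block size < 1")
        t_span = sum(size + dt for size, dt, _ in self.blocks)
        q_span = sum(size + dq for size, _, dq in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ChainParseError(
                f"chain {self.chain_id}: blocks sum to {t_span} source bases, "
                f"header span is {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ChainParseError(
                f"chain {self.chain_id}: blocks sum to {q_span} target bases, "
                f"header span is {self.q_end - self.q_start}"
            )


@dataclass
class MappingResult:
    source: GenomicInterval
    status: str  # "mapped" | "unmapped" | "split"
    target: GenomicInterval | None = None
    mapped_fraction: float = 0.0
    reason: str = ""


class ChainSet:
    """Chains grouped by source chromosome, ordered by descending score."""

    def __init__(self, chains: list[Chain]) -> None:
        self.chains = list(chains)
        self._by_source: dict[str, list[Chain]] = {}
        for ch in self.chains:
            self._by_source.setdefault(ch.t_name, []).append(ch)
        for lst in self._by_source.values():
            lst.sort(key=lambda c: -c.score)

    def overlapping(self, interval: GenomicInterval) -> list[Chain]:
        return [
            ch
            for ch in self._by_source.get(interval.chrom, [])
            if ch.t_start < interval.end and interval.start < ch.t_end
        ]

    def __iter__(self):
        return iter(self.chains)

    def __len__(self) -> int:
        return len(self.chains)


def parse_chain(path) -> list[Chain]:
    """Parse a UCSC chain file, validating block arithmetic per chain."""
    chains: list[Chain] = []
    current: Chain | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                fields = line.split()
                if len(fields) != 13:
                    raise ChainParseError(
                        f"{path}:{lineno}: chain header needs 13 fields, got {len(fields)}"
                    )
                try:
                    current = Chain(
                        score=float(fields[1]),
                        t_name=fields[2],
                        t_size=int(fields[3]),
                        t_strand=fields[4],
                        t_start=int(fields[5]),
                        t_end=int(fields[6]),
                        q_name=fields[7],
                        q_size=int(fields[8]),
                        q_strand=fields[9],
                        q_start=int(fields[10]),
                        q_end=int(fields[11]),
                        chain_id=fields[12],
                    )
                except ValueError as exc:
                    raise ChainParseError(f"{path}:{lineno}: {exc}") from exc
                chains.append(current)
            else:
                if current is None:
                    raise ChainParseError(f"{path}:{lineno}: block line before chain header")
                parts = line.split()
                try:
                    if len(parts) == 3:
                        current.blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                    elif len(parts) == 1:
                        current.blocks.append((int(parts[0]), 0, 0))
                    else:
                        raise ValueError(f"expected 1 or 3 fields, got {len(parts)}")
                except ValueError as exc:
                    raise ChainParseError(f"{path}:{lineno}: {exc}") from exc
    try:
        for ch in chains:
            ch.validate()
    except ChainParseError as exc:
        raise ChainParseError(f"{path}: {exc}") from exc
    return chains


def write_chain(chains: list[Chain], path) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            fh.write(
                f"chain {ch.score:g} {ch.t_name} {ch.t_size} {ch.t_strand} "
                f"{ch.t_start} {ch.t_end} {ch.q_name} {ch.q_size} {ch.q_strand} "
                f"{ch.q_start} {ch.q_end} {ch.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(ch.blocks):
                if i == len(ch.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


def _aligned_segments(chain: Chain):
    """Yield (t_start, t_end, q_start) per block in chain-local q coords."""
    t_pos, q_pos = chain.t_start, chain.q_start
    for size, dt, dq in chain.blocks:
        yield t_pos, t_pos + size, q_pos
        t_pos += size + dt
        q_pos += size + dq


def _q_to_plus(chain: Chain, q_lo: int, q_hi: int) -> tuple[int, int]:
    if chain.q_strand == "-":
        return chain.q_size - q_hi, chain.q_size - q_lo
    return q_lo, q_hi


def map_interval(
    interval: GenomicInterval,
    chains: ChainSet | list[Chain],
    min_match: float = 0.95,
) -> MappingResult:
    """Lift an interval through the best overlapping chain.

    The chain with the highest score among those overlapping the interval is
    used; bases falling in source gaps never map. When the aligned fraction
    is below ``min_match`` the interval is unmapped — with status ``split``
    if other chains also overlapped it (no single chain suffices).
    """
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    cset = chains if isinstance(chains, ChainSet) else ChainSet(list(chains))
    candidates = cset.overlapping(interval)
    if not candidates:
        return MappingResult(interval, "unmapped", reason="no_chain")
    best = candidates[0]
    aligned = 0
    q_first = q_last = None
    for t0, t1, q0 in _aligned_segments(best):
        lo, hi = max(t0, interval.start), min(t1, interval.end)
        if lo < hi:
            aligned += hi - lo
            seg_q_lo = q0 + (lo - t0)
            seg_q_hi = q0 + (hi - t0)
            if q_first is None:
                q_first = seg_q_lo
            q_last = seg_q_hi
    fraction = aligned / len(interval)
    if fraction >= min_match and q_first is not None:
        p_lo, p_hi = _q_to_plus(best, q_first, q_last)
        target = GenomicInterval(
            best.q_name, p_lo, p_hi, interval.id, interval.strand
        )
        return MappingResult(interval, "mapped", target, fraction)
    status = "split" if len(candidates) > 1 and 0 < fraction < min_match else "unmapped"
    reason = "deleted" if aligned == 0 else "below_min_match"
    return MappingResult(interval, status, None, fraction, reason)
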