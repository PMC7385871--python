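"""Monotone coordinate maps between a reference and a modified sequence.

A :class:`ChainMap` records the aligned blocks that survive applying a set
of length-changing alleles (indels) to a reference. It is the same object
a UCSC chain file describes: ordered, non-overlapping blocks that are
strictly increasing in both coordinate systems. SNP substitutions do not
break blocks (the coordinates still correspond); indels do.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .synthpop import ReferenceSequence, Variant


@dataclass
class ChainMap:
    """Blockwise monotone map source (reference) -> target coordinates."""

    blocks: list[tuple[int, int, int]]  # (src_start, tgt_start, length)
    src_len: int
    tgt_len: int

    def __post_init__(self) -> None:
        prev_s = prev_t = -1
        for s, t, ln in self.blocks:
            if ln <= 0 or s <= prev_s or t <= prev_t:
                raise ValueError("chain blocks must be increasing, positive length")
            prev_s, prev_t = s + ln - 1, t + ln - 1
        self._src_starts = [b[0] for b in self.blocks]
        self._tgt_starts = [b[1] for b in self.blocks]

    # -- point lookups ----------------------------------------------
    def forward(self, pos: int) -> int | None:
        """Map a source position to target; None inside deleted material."""
        return self._map(pos, self._src_starts, 0, 1, self.src_len)

    def reverse(self, pos: int) -> int | None:
        """Map a target position back to source; None inside insertions."""
        return self._map(pos, self._tgt_starts, 1, 0, self.tgt_len)

    def _map(self, pos, starts, i_from, i_to, limit) -> int | None:
        if pos < 0 or pos >= limit:
            raise ValueError(f"position {pos} outside sequence of length {limit}")
        k = bisect.bisect_right(starts, pos) - 1
        if k < 0:
            return None
        blk = self.blocks[k]
        off = pos - blk[i_from]
        if off >= blk[2]:
            return None
        return blk[i_to] + off

    def project(self, pos: int, direction: str = "forward") -> int:
        """Nearest mapped coordinate at or left of ``pos`` (surjection rule).

        Positions inside unmapped material are assigned the coordinate of
        the preceding aligned base; positions before the first block map
        to the first block's start.
        """
        if direction == "forward":
            starts, i_from, i_to, limit = self._src_starts, 0, 1, self.src_len
        else:
            starts, i_from, i_to, limit = self._tgt_starts, 1, 0, self.tgt_len
        if pos < 0 or pos >= limit:
            raise ValueError(f"position {pos} outside sequence of length {limit}")
        k = bisect.bisect_right(starts, pos) - 1
        if k < 0:
            return self.blocks[0][i_to]
        blk = self.blocks[k]
        off = min(pos - blk[i_from], blk[2] - 1)
        return blk[i_to] + off

    def first_mapped(self, start: int, end: int, direction: str = "reverse") -> int | None:
        """Mapped image of the first mappable position in [start, end)."""
        fn = self.forward if direction == "forward" else self.reverse
        for p in range(start, min(end, self.tgt_len if direction == "reverse" else self.src_len)):
            m = fn(p)
            if m is not None:
                return m
        return None

    def invert(self) -> "ChainMap":
        return ChainMap(
            [(t, s, ln) for s, t, ln in self.blocks], self.tgt_len, self.src_len
        )


def liftover(chain: ChainMap, pos: int, direction: str = "forward") -> int | None:
    """Map a coordinate through a chain; None when it falls in a gap."""
    if direction == "forward":
        return chain.forward(pos)
    if direction == "reverse":
        return chain.reverse(pos)
    raise ValueError("direction must be 'forward' or 'reverse'")


def apply_alleles(
    ref: ReferenceSequence | str,
    variants: list[Variant],
) -> tuple[str, ChainMap]:
    """Apply alternate alleles left-to-right; return sequence and chain.

    ``variants`` must be position-sorted and non-overlapping. SNPs keep
    the coordinate correspondence; for indels the leading anchor base
    stays aligned and the inserted/deleted remainder becomes a gap.
    """
    seq = ref.sequence if isinstance(ref, ReferenceSequence) else ref
    out: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    src = tgt = 0
    block_src = block_tgt = 0

    def close_block(upto_src: int, upto_tgt: int) -> None:
        ln = upto_src - block_src
        if ln > 0:
            blocks.append((block_src, block_tgt, ln))

    prev_end = 0
    for v in variants:
        if v.pos < prev_end:
            raise ValueError(f"overlapping variants near {v.pos}")
        if v.end > len(seq):
            raise ValueError(f"variant at {v.pos} outside reference")
        prev_end = v.end
        out.append(seq[src : v.pos])
        tgt += v.pos - src
        src = v.pos
        if v.length_delta == 0:  # SNP: substitute, block continues
            out.append(v.alt)
            src += len(v.ref)
            tgt += len(v.alt)
            continue
        # anchored indel: anchor stays aligned, remainder is a gap
        anchor = min(len(v.ref), len(v.alt))
        out.append(v.alt)
        close_block(src + anchor, None)
        src += len(v.ref)
        tgt += len(v.alt)
        block_src, block_tgt = src, tgt
    out.append(seq[src:])
    tgt += len(seq) - src
    src = len(seq)
    close_block(src, None)
    new_seq = "".join(out)
    assert tgt == len(new_seq)
    return new_seq, ChainMap(blocks, len(seq), len(new_seq))
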