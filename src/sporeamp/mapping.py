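"""Read placement on the reference amplicon under explicit edit costs.

Alignment is local (read ends may be soft-clipped, reference ends are free)
and maximises the score

    +1 per match  -  mismatch_cost (2) per mismatch  -  indel cost (3) per
    inserted or deleted base,

the cost scheme of desktop read mappers configured with mismatch cost 2 and
insertion/deletion cost 3. Soft-clipped bases (e.g. primer/adapter remnants)
count against the aligned-read fraction but not against identity. A read is
accepted ("mapped") when

    aligned_read_fraction >= length_fraction     (default 0.5)
    identity_fraction     >= similarity_fraction (default 0.8)

Both orientations are tried; ties in score — between orientations or between
equally good placements — are broken uniformly by a per-read seeded generator,
i.e. non-specific matches map randomly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pysam
from Bio.SeqRecord import SeqRecord

from ._util import revcomp, round_half_away


class MappingError(ValueError):
    pass


@dataclass
class MappingParams:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.5
    similarity_fraction: float = 0.8
    nonspecific_handling: str = "random"
    seed: int = 0

    def validate(self) -> None:
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise MappingError("costs must be positive")
        for f in (self.length_fraction, self.similarity_fraction):
            if not 0 < f <= 1:
                raise MappingError("fractions must be in (0,1]")


@dataclass
class AlignmentRecord:
    """A placed (or rejected) read, stored in reference orientation.

    ``ops`` is a run-length list of ('=' match, 'X' mismatch, 'I' read
    insertion, 'D' reference deletion, 'S' soft clip) covering the whole read.
    """

    read_id: str
    mapped: bool
    ref_start: int                      # 1-based; 0 when unmapped
    ops: list[tuple[str, int]]
    aligned_read_fraction: float
    identity_fraction: float
    seq: str                            # reference-orientation sequence
    qualities: list[int]
    reverse: bool = False
    cost: int = 0        # edit cost of the aligned region: 2*mm + 3*gap bases
    score: int = 0       # local alignment score: matches - cost

    @property
    def ref_end(self) -> int:
        """Last reference base consumed (1-based inclusive)."""
        consumed = sum(n for op, n in self.ops if op in ("=", "X", "D"))
        return self.ref_start + consumed - 1

    def walk(self):
        """Yield (op, ref_pos, read_idx0) per aligned unit for pileup building."""
        r = self.ref_start
        i = 0
        for op, n in self.ops:
            for _ in range(n):
                if op in ("=", "X"):
                    yield (op, r, i)
                    r += 1
                    i += 1
                elif op == "D":
                    yield (op, r, i)
                    r += 1
                else:  # I or S consume the read only
                    yield (op, r, i)
                    i += 1


@dataclass
class MappingStats:
    n_reads: int
    n_mapped: int
    percent_mapped: int
    mean_mapped_read_length: int | None


# -- quality trimming --------------------------------------------------------

def trim_reads(reads: Sequence[SeqRecord], quality: int = 20,
               min_length: int = 50) -> list[SeqRecord]:
    """Phred end-trim: strip bases below ``quality`` from both read ends and
    drop reads shorter than ``min_length`` after trimming."""
    out = []
    for rec in reads:
        quals = rec.letter_annotations["phred_quality"]
        lo, hi = 0, len(quals)
        while lo < hi and quals[lo] < quality:
            lo += 1
        while hi > lo and quals[hi - 1] < quality:
            hi -= 1
        if hi - lo >= min_length:
            out.append(rec[lo:hi])
    return out


# -- core alignment ----------------------------------------------------------

def _read_rng(seed: int, read_id: str) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), zlib.crc32(read_id.encode())])


def _dp_matrix(read: str, ref: str, params: MappingParams) -> np.ndarray:
    """Local-alignment score matrix (rows = read prefix, cols = ref prefix).

    H[i][j] = best score of any local alignment ending with read base i on
    reference base j (or 0). Row recurrences are vectorised; the linear
    deletion gap along the reference is a prefix-max scan.
    """
    m, n = len(read), len(ref)
    mc, ic, dc = params.mismatch_cost, params.insertion_cost, params.deletion_cost
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    dp = np.zeros((m + 1, n + 1), dtype=np.int32)
    js = np.arange(n + 1, dtype=np.int64) * dc
    for i in range(1, m + 1):
        prev = dp[i - 1]
        sub = np.where(ref_arr == ord(read[i - 1]), 1, -mc).astype(np.int64)
        cand = np.maximum(prev[:-1] + sub, prev[1:] - ic)
        t = np.empty(n + 1, dtype=np.int64)
        t[0] = 0
        t[1:] = cand + js[1:]
        np.maximum.accumulate(t, out=t)
        row = t - js
        np.maximum(row, 0, out=row)
        row[0] = 0
        dp[i] = row
    return dp


def _traceback(dp: np.ndarray, read: str, ref: str, params: MappingParams,
               end_i: int, end_j: int) -> tuple[int, list[tuple[str, int]]]:
    """Recover one optimal local path ending at (end_i, end_j); returns the
    1-based reference start and the run-length op list covering the whole
    read (clipped ends as S)."""
    mc, ic, dc = params.mismatch_cost, params.insertion_cost, params.deletion_cost
    m = len(read)
    ops: list[str] = []
    if end_i < m:
        ops.extend("S" * (m - end_i))
    i, j = end_i, end_j
    last = ""
    while i > 0 and j > 0 and dp[i, j] > 0:
        v = dp[i, j]
        moves = {
            "M": i > 0 and j > 0 and v == dp[i - 1, j - 1]
                 + (1 if read[i - 1] == ref[j - 1] else -mc),
            "D": j > 0 and v == dp[i, j - 1] - dc,
            "I": i > 0 and v == dp[i - 1, j] - ic,
        }
        # among equal-score moves, extend an open gap run first so indels
        # stay contiguous; otherwise prefer the diagonal
        order = {"D": "DMI", "I": "IMD"}.get(last, "MDI")
        move = next((mv for mv in order if moves[mv]), None)
        if move is None:  # pragma: no cover - defensive
            raise MappingError("traceback failed")
        if move == "M":
            ops.append("=" if read[i - 1] == ref[j - 1] else "X")
            i -= 1
            j -= 1
        elif move == "D":
            ops.append("D")
            j -= 1
        else:
            ops.append("I")
            i -= 1
        last = move
    if i > 0:
        ops.extend("S" * i)  # left clip
    ops.reverse()
    ref_start = j + 1
    rle: list[tuple[str, int]] = []
    for op in ops:
        if rle and rle[-1][0] == op:
            rle[-1] = (op, rle[-1][1] + 1)
        else:
            rle.append((op, 1))
    return ref_start, rle


def _best_endpoints(dp: np.ndarray) -> tuple[int, list[tuple[int, int]]]:
    """Maximum score over all cells, with every argmax cell (equally good
    local placements)."""
    best = int(dp.max())
    cells = [(int(i), int(j)) for i, j in np.argwhere(dp == best)]
    return best, cells


def _exact_placements(read: str, ref: str) -> list[int]:
    """All 0-based start positions where the read is an exact substring."""
    out = []
    start = ref.find(read)
    while start != -1:
        out.append(start)
        start = ref.find(read, start + 1)
    return out


def _align_oriented(read: str, ref: str, params: MappingParams):
    """Return (score, candidate end cells or exact starts, dp or None).

    A full-length exact match attains the maximum possible score len(read),
    so the substring fast path is exhaustive when it fires.
    """
    exact = _exact_placements(read, ref)
    if exact:
        return len(read), exact, None
    dp = _dp_matrix(read, ref, params)
    score, cells = _best_endpoints(dp)
    return score, cells, dp


def _record_from_path(read_id: str, seq: str, quals: list[int], ref: str,
                      params: MappingParams, ref_start: int,
                      rle: list[tuple[str, int]],
                      reverse: bool) -> AlignmentRecord:
    matches = sum(n for op, n in rle if op == "=")
    mismatches = sum(n for op, n in rle if op == "X")
    gaps = sum(n for op, n in rle if op in ("I", "D"))
    clipped = sum(n for op, n in rle if op == "S")
    read_len = len(seq)
    aligned_fraction = (read_len - clipped) / read_len
    denom = matches + mismatches + gaps
    identity = matches / denom if denom else 0.0
    cost = params.mismatch_cost * mismatches + sum(
        n * (params.insertion_cost if op == "I" else params.deletion_cost)
        for op, n in rle if op in ("I", "D"))
    mapped = (denom > 0
              and aligned_fraction >= params.length_fraction
              and identity >= params.similarity_fraction)
    return AlignmentRecord(read_id, mapped, ref_start, rle, aligned_fraction,
                           identity, seq, quals, reverse, cost, matches - cost)


def align_read(read: SeqRecord | str, reference: str,
               params: MappingParams | None = None,
               qualities: list[int] | None = None) -> AlignmentRecord:
    """Minimum-cost placement of one read (both orientations) on the reference."""
    params = params or MappingParams()
    params.validate()
    if isinstance(read, SeqRecord):
        read_id = read.id
        seq = str(read.seq).upper()
        quals = list(read.letter_annotations.get("phred_quality", [30] * len(seq)))
    else:
        read_id = "read"
        seq = str(read).upper()
        quals = qualities if qualities is not None else [30] * len(seq)
    if len(seq) < 1:
        raise MappingError("empty read")
    if len(reference) < 1:
        raise MappingError("empty reference")
    reference = reference.upper()
    rng = _read_rng(params.seed, read_id)

    rc_seq = revcomp(seq)
    fwd_exact = _exact_placements(seq, reference)
    rev_exact = _exact_placements(rc_seq, reference)
    if fwd_exact or rev_exact:
        # a full-length exact match attains the maximum possible score, so
        # the other orientation can at best tie (by also being exact)
        fwd = (len(seq) if fwd_exact else -1, fwd_exact, None)
        rev = (len(seq) if rev_exact else -1, rev_exact, None)
    else:
        fwd = _align_oriented(seq, reference, params)
        rev = _align_oriented(rc_seq, reference, params)

    candidates = []  # (orientation, score, cells, dp, oriented_seq, oriented_quals)
    if fwd[0] >= rev[0]:
        candidates.append((False, *fwd, seq, quals))
    if rev[0] >= fwd[0]:
        candidates.append((True, *rev, rc_seq, list(reversed(quals))))
    pick = candidates[int(rng.integers(0, len(candidates)))] if len(candidates) > 1 \
        else candidates[0]
    reverse, score, cells, dp, oseq, oquals = pick

    if score <= 0:  # nothing aligns: report the read unplaced
        return AlignmentRecord(read_id, False, 0, [("S", len(oseq))], 0.0, 0.0,
                               seq, quals, False, 0, 0)
    choice = cells[int(rng.integers(0, len(cells)))] if len(cells) > 1 else cells[0]
    if dp is None:  # exact substring; choice is a 0-based start
        rle = [("=", len(oseq))]
        ref_start = choice + 1
    else:
        ref_start, rle = _traceback(dp, oseq, reference, params, *choice)
    return _record_from_path(read_id, oseq, oquals, reference, params,
                             ref_start, rle, reverse)


def map_all(reads: Sequence[SeqRecord], reference: str,
            params: MappingParams | None = None,
            sam_path=None, ref_name: str = "amplicon"
            ) -> tuple[list[AlignmentRecord], MappingStats]:
    """Align every read; optionally write SAM; compute Table-1-style stats."""
    params = params or MappingParams()
    if not reads:
        raise MappingError("no reads to map")
    records = [align_read(r, reference, params) for r in reads]
    stats = mapping_stats(records)
    if sam_path is not None:
        write_sam(records, reference, sam_path, ref_name)
    return records, stats


def mapping_stats(records: Sequence[AlignmentRecord]) -> MappingStats:
    n = len(records)
    mapped = [r for r in records if r.mapped]
    pct = round_half_away(100.0 * len(mapped) / n) if n else 0
    mean_len = (round_half_away(sum(len(r.seq) for r in mapped) / len(mapped))
                if mapped else None)
    return MappingStats(n, len(mapped), pct, mean_len)


# -- SAM IO ------------------------------------------------------------------

_SAM_OP = {"=": "M", "X": "M", "I": "I", "D": "D", "S": "S"}


def _cigar_string(ops: list[tuple[str, int]]) -> str:
    # collapse adjacent =/X runs into M
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        sam_op = _SAM_OP[op]
        if merged and merged[-1][0] == sam_op:
            merged[-1] = (sam_op, merged[-1][1] + n)
        else:
            merged.append((sam_op, n))
    return "".join(f"{n}{op}" for op, n in merged)


def write_sam(records: Sequence[AlignmentRecord], reference: str, path,
              ref_name: str = "amplicon") -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref_name, "LN": len(reference)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.query_qualities = list(r.qualities)
            if r.mapped:
                a.flag = 16 if r.reverse else 0
                a.reference_id = 0
                a.reference_start = r.ref_start - 1
                a.mapping_quality = 60
                a.cigarstring = _cigar_string(r.ops)
                nm = sum(n for op, n in r.ops if op in ("X", "I", "D"))
                a.set_tag("NM", nm)
                a.set_tag("XC", r.cost)
            else:
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            out.write(a)


def read_sam(path, reference: str,
             params: MappingParams | None = None) -> list[AlignmentRecord]:
    """Rebuild :class:`AlignmentRecord`s from SAM; M runs are re-split into
    match/mismatch against the reference, so fields round-trip exactly."""
    reference = reference.upper()
    params = params or MappingParams()
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            seq = a.query_sequence or ""
            quals = list(a.query_qualities) if a.query_qualities is not None else []
            if a.is_unmapped:
                out.append(AlignmentRecord(a.query_name, False, 0, [], 0.0, 0.0,
                                           seq, quals, False, 0))
                continue
            ref_start = a.reference_start + 1
            ops: list[tuple[str, int]] = []
            r, i = ref_start, 0
            for op_code, n in a.cigartuples:
                op = "MIDNSHP=X"[op_code]
                if op == "M":
                    for k in range(n):
                        kind = "=" if seq[i + k] == reference[r - 1 + k] else "X"
                        if ops and ops[-1][0] == kind:
                            ops[-1] = (kind, ops[-1][1] + 1)
                        else:
                            ops.append((kind, 1))
                    r += n
                    i += n
                elif op in ("=", "X", "I", "S"):
                    ops.append((op, n))
                    i += n
                    if op in ("=", "X"):
                        r += n
                elif op == "D":
                    ops.append(("D", n))
                    r += n
            rec = _record_from_path(a.query_name, seq, quals, reference, params,
                                    ref_start, ops, a.is_reverse)
            out.append(rec)
    return out
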