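"""Reference-projected read alignments.

The pipeline's stages (coverage, calling, allele partitioning, window
screening) all consume alignments through a small positional contract:
*which reads cover a site, with which base*, and *which reads overlap an
interval*.  :class:`ReadSet` implements that contract over a compact
columnar representation in which every query base is projected onto a
reference coordinate:

* query index ``j`` of read ``r`` corresponds to reference position
  ``qstart[r] + j`` (modulo the reference length on circular genomes);
* ``left_clip``/``right_clip`` mark soft-clipped prefixes/suffixes that are
  present in the query but not aligned;
* deletions in ingested alignments are represented by pad codes so that
  the linear query<->reference mapping is preserved (deleted columns
  contribute no base, matching pileup semantics).

Simulated reads are gap-free, so the projection is exact; for ingested
SAM/BAM records, insertions are dropped from the projection (they consume
no reference) and deletions are padded.  This mirrors how a pileup engine
walks CIGAR strings.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pysam

#: base encoding used throughout the package
BASES = "ACGT"
PAD = np.uint8(255)
N_CODE = np.uint8(4)

_ENCODE_LUT = np.full(256, PAD, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_ENCODE_LUT[ord("N")] = N_CODE
_ENCODE_LUT[ord("n")] = N_CODE

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_CHUNK = 65536


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode_codes(codes: np.ndarray) -> str:
    """Decode uint8 codes back to a nucleotide string (pads become ``N``)."""
    codes = np.asarray(codes, dtype=np.uint8)
    safe = np.where(codes > 4, N_CODE, codes)
    return _DECODE[safe].tobytes().decode("ascii")


class ReadSet:
    """A set of reads aligned to one reference sequence.

    Parameters
    ----------
    reference:
        Name of the reference the reads are aligned to.
    ref_length:
        Reference length in bp.
    circular:
        Whether reference coordinates wrap.
    qstart:
        Reference coordinate assigned to query index 0 of each read (the
        leftmost *aligned* base sits at ``qstart + left_clip``).
    qlen:
        Projected query length per read (clips + reference span).
    left_clip, right_clip:
        Soft/hard-clipped prefix and suffix lengths.
    codes:
        ``(n, max_qlen)`` uint8 base codes, padded with 255.
    reverse, proper, mate2:
        SAM-flag derived booleans (reverse strand, proper pair, second
        mate).  Defaults: forward, proper, first mate.
    quals:
        Optional per-base qualities aligned with ``codes``.  ``None``
        means qualities are unknown and treated as passing any floor.
    names:
        Optional read names (generated on export when absent).
    sample:
        Optional sample label carried along for reporting.
    """

    def __init__(
        self,
        reference: str,
        ref_length: int,
        circular: bool,
        qstart: np.ndarray,
        qlen: np.ndarray,
        left_clip: np.ndarray,
        right_clip: np.ndarray,
        codes: np.ndarray,
        reverse: np.ndarray | None = None,
        proper: np.ndarray | None = None,
        mate2: np.ndarray | None = None,
        quals: np.ndarray | None = None,
        names: Sequence[str] | None = None,
        sample: str | None = None,
        ref_codes: np.ndarray | None = None,
    ) -> None:
        n = len(qstart)
        self.reference = reference
        self.ref_length = int(ref_length)
        self.circular = bool(circular)
        self.qstart = np.asarray(qstart, dtype=np.int64)
        if self.circular:
            self.qstart = self.qstart % self.ref_length
        self.qlen = np.asarray(qlen, dtype=np.int64)
        self.left_clip = np.asarray(left_clip, dtype=np.int64)
        self.right_clip = np.asarray(right_clip, dtype=np.int64)
        self.codes = np.asarray(codes, dtype=np.uint8)
        if self.codes.shape[0] != n:
            raise ValueError("codes row count does not match read count")
        self.reverse = self._flag(reverse, n, False)
        self.proper = self._flag(proper, n, True)
        self.mate2 = self._flag(mate2, n, False)
        self.quals = None if quals is None else np.asarray(quals, dtype=np.uint8)
        self.names = list(names) if names is not None else None
        self.sample = sample
        #: reference sequence codes, when known (enables the sparse fast path)
        self.ref_codes = ref_codes
        self._nm: np.ndarray | None = None
        self._counts: np.ndarray | None = None
        if np.any(self.left_clip + self.right_clip > self.qlen):
            raise ValueError("clip lengths exceed query length")

    @staticmethod
    def _flag(values, n: int, default: bool) -> np.ndarray:
        if values is None:
            return np.full(n, default, dtype=bool)
        return np.asarray(values, dtype=bool)

    # ------------------------------------------------------------------
    # basic geometry
    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.qstart)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n

    @property
    def aligned_start(self) -> np.ndarray:
        start = self.qstart + self.left_clip
        if self.circular:
            start = start % self.ref_length
        return start

    @property
    def span(self) -> np.ndarray:
        """Reference-consuming length of each read's aligned segment."""
        return self.qlen - self.left_clip - self.right_clip

    @property
    def clipped(self) -> np.ndarray:
        return (self.left_clip > 0) | (self.right_clip > 0)

    # ------------------------------------------------------------------
    # positional queries
    # ------------------------------------------------------------------
    def _positions(self, rows: slice) -> np.ndarray:
        ar = np.arange(self.codes.shape[1], dtype=np.int64)
        pos = self.qstart[rows, None] + ar
        if self.circular:
            pos %= self.ref_length
        return pos

    def _depth_from_intervals(self) -> np.ndarray:
        """Aligned-span depth by interval accounting (gap-free fast path)."""
        L = self.ref_length
        starts = self.aligned_start
        ends = starts + self.span
        delta = np.zeros(L + 1, dtype=np.int64)
        np.add.at(delta, starts, 1)
        np.add.at(delta, np.minimum(ends, L), -1)
        depth = np.cumsum(delta[:L])
        if self.circular:
            wrapped = ends[ends > L] - L
            if len(wrapped):
                delta2 = np.zeros(L + 1, dtype=np.int64)
                delta2[0] = len(wrapped)
                np.add.at(delta2, wrapped, -1)
                depth += np.cumsum(delta2[:L])
        return depth

    def _scan_mismatches(self) -> None:
        """Sparse pass comparing reads to the reference (fast path).

        Fills the base-count matrix and per-read mismatch totals in one
        chunked sweep: depth comes from interval accounting, and only
        the cells where a read differs from the reference are touched
        individually.  Requires ``ref_codes`` and no quality filtering.
        """
        L = self.ref_length
        maxlen = self.codes.shape[1]
        ext = np.concatenate([self.ref_codes, self.ref_codes[:maxlen]]) if self.circular else self.ref_codes
        ar = np.arange(maxlen, dtype=np.int32)
        qstart32 = self.qstart.astype(np.int32)
        nonref = np.zeros(5 * L, dtype=np.int64)
        nm = np.zeros(self.n, dtype=np.int64)
        for lo in range(0, self.n, _CHUNK):
            hi = min(lo + _CHUNK, self.n)
            rows = slice(lo, hi)
            codes = self.codes[rows]
            pos = qstart32[rows, None] + ar
            aligned = (
                (ar >= self.left_clip[rows, None])
                & (ar < (self.qlen[rows] - self.right_clip[rows])[:, None])
            )
            if not self.circular:
                aligned &= (pos >= 0) & (pos < L)
            ref = ext[np.clip(pos, 0, len(ext) - 1)]
            mism = aligned & (codes != ref) & (codes <= 3)
            r, c = np.nonzero(mism)
            nm[lo:hi] = np.bincount(r, minlength=hi - lo)
            p = pos[r, c].astype(np.int64) % L
            key = codes[r, c].astype(np.int64) * L + p
            nonref += np.bincount(key, minlength=5 * L)
        counts = nonref.reshape(5, L)
        depth = self._depth_from_intervals()
        cols = np.arange(L)
        own = depth - counts[:4].sum(axis=0)
        counts[self.ref_codes[cols], cols] += own
        self._counts = counts
        if self._nm is None:
            self._nm = nm

    def base_counts(self, min_baseq: int = 0) -> np.ndarray:
        """Per-position base counts as a ``(5, L)`` matrix (A,C,G,T,N rows).

        Only aligned (non-clipped, non-pad) bases are counted; with
        qualities present, bases below ``min_baseq`` are skipped.
        Results for ``min_baseq == 0`` are cached.
        """
        if min_baseq == 0 and self._counts is not None:
            return self._counts
        if (
            min_baseq == 0
            and self.ref_codes is not None
            and self.quals is None
            and self.n > 0
        ):
            self._scan_mismatches()
            return self._counts
        L = self.ref_length
        counts = np.zeros(5 * L, dtype=np.int64)
        m = self.codes.shape[1]
        ar = np.arange(m, dtype=np.int64)
        for lo in range(0, self.n, _CHUNK):
            rows = slice(lo, min(lo + _CHUNK, self.n))
            codes = self.codes[rows]
            pos = self._positions(rows)
            aligned = (
                (ar >= self.left_clip[rows, None])
                & (ar < (self.qlen[rows] - self.right_clip[rows])[:, None])
                & (codes <= 4)
                & (pos >= 0)
                & (pos < L)
            )
            if min_baseq > 0 and self.quals is not None:
                aligned &= self.quals[rows] >= min_baseq
            idx = codes[aligned].astype(np.int64) * L + pos[aligned]
            counts += np.bincount(idx, minlength=5 * L)
        result = counts.reshape(5, L)
        if min_baseq == 0:
            self._counts = result
        return result

    def depth(self, min_baseq: int = 0) -> np.ndarray:
        """Per-position depth of called (A/C/G/T) bases."""
        return self.base_counts(min_baseq)[:4].sum(axis=0)

    def total_aligned_bases(self, min_baseq: int = 0) -> int:
        """Total number of aligned called bases (the depth mass)."""
        return int(self.base_counts(min_baseq)[:4].sum())

    def reads_covering(self, position: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices and query offsets of reads whose aligned span covers ``position``."""
        off = position - self.qstart
        if self.circular:
            off %= self.ref_length
        mask = (off >= self.left_clip) & (off < self.qlen - self.right_clip)
        idx = np.flatnonzero(mask)
        return idx, off[idx]

    def bases_at(self, position: int) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Read indices, base codes and qualities at a reference position."""
        idx, off = self.reads_covering(position)
        base = self.codes[idx, off]
        qual = self.quals[idx, off] if self.quals is not None else None
        return idx, base, qual

    def reads_overlapping(self, start: int, end: int) -> np.ndarray:
        """Indices of reads whose aligned span overlaps ``[start, end)`` by >= 1 bp."""
        astart = self.aligned_start
        span = self.span
        nonempty = span > 0
        if self.circular:
            L = self.ref_length
            w = min(end - start, L)
            rel1 = (astart - start) % L
            rel2 = (start - astart) % L
            mask = nonempty & ((rel1 < w) | (rel2 < span))
        else:
            mask = nonempty & (astart < end) & (astart + span > start)
        return np.flatnonzero(mask)

    def subset(self, idx: np.ndarray) -> "ReadSet":
        return ReadSet(
            self.reference,
            self.ref_length,
            self.circular,
            self.qstart[idx],
            self.qlen[idx],
            self.left_clip[idx],
            self.right_clip[idx],
            self.codes[idx],
            self.reverse[idx],
            self.proper[idx],
            self.mate2[idx],
            None if self.quals is None else self.quals[idx],
            None if self.names is None else [self.names[i] for i in idx],
            self.sample,
            self.ref_codes,
        )

    # ------------------------------------------------------------------
    # mismatch accounting
    # ------------------------------------------------------------------
    def set_nm(self, nm: np.ndarray) -> None:
        self._nm = np.asarray(nm, dtype=np.int64)

    def nm_array(self, genome_codes: np.ndarray | None = None) -> np.ndarray:
        """Per-read mismatch count versus the reference over the aligned span.

        Uses the value provided by the simulator or the NM tag when
        available, otherwise recomputes it against ``genome_codes``.
        """
        if self._nm is not None:
            return self._nm
        if self.ref_codes is not None and self.quals is None and self.n > 0:
            self._scan_mismatches()
            return self._nm
        if genome_codes is None:
            raise ValueError("mismatch counts unavailable; provide the reference sequence")
        nm = np.zeros(self.n, dtype=np.int64)
        ar = np.arange(self.codes.shape[1], dtype=np.int64)
        L = self.ref_length
        for lo in range(0, self.n, _CHUNK):
            rows = slice(lo, min(lo + _CHUNK, self.n))
            codes = self.codes[rows]
            pos = self._positions(rows)
            aligned = (
                (ar >= self.left_clip[rows, None])
                & (ar < (self.qlen[rows] - self.right_clip[rows])[:, None])
                & (codes <= 3)
                & (pos >= 0)
                & (pos < L)
            )
            ref = genome_codes[np.clip(pos, 0, L - 1)]
            mism = aligned & (codes != ref)
            nm[rows] = mism.sum(axis=1)
        self._nm = nm
        return nm

    # ------------------------------------------------------------------
    # SAM interchange
    # ------------------------------------------------------------------
    def _sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": self.reference, "LN": self.ref_length}],
            }
        )

    def to_sam(self, path: str, genome_codes: np.ndarray | None = None) -> None:
        """Write the read set as a coordinate-sorted SAM file.

        On circular references, alignments that would run past the end of
        the contig are represented with the overhang soft-clipped, the way
        a linear aligner would report them.
        """
        header = self._sam_header()
        nm = self._nm
        if nm is None and genome_codes is not None:
            nm = self.nm_array(genome_codes)
        order = np.argsort(self.aligned_start, kind="stable")
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for i in order:
                seg = pysam.AlignedSegment(header)
                if self.names is not None:
                    seg.query_name = self.names[i]
                else:
                    seg.query_name = f"r{i:09d}"
                lc = int(self.left_clip[i])
                rc = int(self.right_clip[i])
                qlen = int(self.qlen[i])
                span = qlen - lc - rc
                pos = int(self.aligned_start[i])
                # linearise wrap-around alignments by clipping the overhang
                overhang = max(0, pos + span - self.ref_length)
                span -= overhang
                rc += overhang
                flag = 0x1
                if self.proper[i]:
                    flag |= 0x2
                if self.reverse[i]:
                    flag |= 0x10
                flag |= 0x80 if self.mate2[i] else 0x40
                seg.flag = flag
                seg.reference_id = 0
                seg.reference_start = pos
                seg.mapping_quality = 60
                cigar = []
                if lc:
                    cigar.append((4, lc))
                cigar.append((0, span))
                if rc:
                    cigar.append((4, rc))
                seg.cigartuples = cigar
                codes = self.codes[i, :qlen]
                seg.query_sequence = decode_codes(codes)
                if self.quals is not None:
                    seg.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in self.quals[i, :qlen])
                    )
                else:
                    seg.query_qualities = pysam.qualitystring_to_array("I" * qlen)
                if nm is not None:
                    seg.set_tag("NM", int(nm[i]))
                out.write(seg)

    @classmethod
    def from_alignment_file(
        cls,
        path: str,
        reference: str | None = None,
        circular: bool = False,
        sample: str | None = None,
    ) -> "ReadSet":
        """Load primary mapped alignments from a SAM/BAM file.

        Insertions are dropped from the reference projection and deletions
        are padded, so per-site base queries follow pileup semantics.
        """
        mode = "rb" if path.endswith(".bam") else "r"
        records: list[tuple] = []
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            refs = {name: length for name, length in zip(fh.references, fh.lengths)}
            if reference is None:
                if len(refs) != 1:
                    raise ValueError("multiple references in file; specify one")
                reference = next(iter(refs))
            if reference not in refs:
                raise ValueError(f"reference {reference!r} absent from alignment header")
            ref_length = refs[reference]
            for seg in fh.fetch(until_eof=True):
                if (
                    seg.is_unmapped
                    or seg.is_secondary
                    or seg.is_supplementary
                    or seg.reference_name != reference
                ):
                    continue
                records.append(_project_segment(seg))
        n = len(records)
        if n == 0:
            return cls.empty(reference, ref_length, circular, sample=sample)
        max_qlen = max(r[1] for r in records)
        codes = np.full((n, max_qlen), PAD, dtype=np.uint8)
        quals = np.zeros((n, max_qlen), dtype=np.uint8)
        qstart = np.zeros(n, dtype=np.int64)
        qlen = np.zeros(n, dtype=np.int64)
        lclip = np.zeros(n, dtype=np.int64)
        rclip = np.zeros(n, dtype=np.int64)
        reverse = np.zeros(n, dtype=bool)
        proper = np.zeros(n, dtype=bool)
        mate2 = np.zeros(n, dtype=bool)
        nm = np.full(n, -1, dtype=np.int64)
        names = []
        for i, rec in enumerate(records):
            (qstart[i], qlen[i], lclip[i], rclip[i], row_codes, row_quals,
             reverse[i], proper[i], mate2[i], nm[i], name) = rec
            codes[i, : len(row_codes)] = row_codes
            quals[i, : len(row_quals)] = row_quals
            names.append(name)
        rs = cls(
            reference, ref_length, circular, qstart, qlen, lclip, rclip,
            codes, reverse, proper, mate2, quals, names, sample,
        )
        if np.all(nm >= 0):
            rs.set_nm(nm)
        return rs

    @classmethod
    def empty(
        cls, reference: str, ref_length: int, circular: bool = False, sample: str | None = None
    ) -> "ReadSet":
        z = np.zeros(0, dtype=np.int64)
        return cls(
            reference, ref_length, circular, z, z, z, z,
            np.zeros((0, 1), dtype=np.uint8), sample=sample,
        )


def _project_segment(seg: pysam.AlignedSegment) -> tuple:
    """Project a pysam record onto the linear query<->reference layout."""
    seq = seg.query_sequence or ""
    q = encode_sequence(seq)
    quals = seg.query_qualities
    quals = np.asarray(quals, dtype=np.uint8) if quals is not None else np.full(len(q), 40, np.uint8)
    out_codes: list[np.ndarray] = []
    out_quals: list[np.ndarray] = []
    lclip = 0
    rclip = 0
    qi = 0
    seen_match = False
    for op, length in seg.cigartuples or []:
        if op in (4, 5):  # S/H
            if not seen_match:
                lclip += length
                if op == 4:
                    out_codes.append(q[qi : qi + length])
                    out_quals.append(quals[qi : qi + length])
                    qi += length
                else:
                    out_codes.append(np.full(length, PAD, np.uint8))
                    out_quals.append(np.zeros(length, np.uint8))
            else:
                rclip += length
                if op == 4:
                    out_codes.append(q[qi : qi + length])
                    out_quals.append(quals[qi : qi + length])
                    qi += length
                else:
                    out_codes.append(np.full(length, PAD, np.uint8))
                    out_quals.append(np.zeros(length, np.uint8))
        elif op in (0, 7, 8):  # M/=/X
            seen_match = True
            out_codes.append(q[qi : qi + length])
            out_quals.append(quals[qi : qi + length])
            qi += length
        elif op == 1:  # I: consumes query only
            qi += length
        elif op == 2 or op == 3:  # D/N: consumes reference only -> pad
            seen_match = True
            out_codes.append(np.full(length, PAD, np.uint8))
            out_quals.append(np.zeros(length, np.uint8))
        # P (6) consumes nothing
    row_codes = np.concatenate(out_codes) if out_codes else np.zeros(0, np.uint8)
    row_quals = np.concatenate(out_quals) if out_quals else np.zeros(0, np.uint8)
    qstart = seg.reference_start - lclip
    nm = seg.get_tag("NM") if seg.has_tag("NM") else -1
    return (
        qstart,
        len(row_codes),
        lclip,
        rclip,
        row_codes,
        row_quals,
        seg.is_reverse,
        seg.is_proper_pair,
        seg.is_read2,
        nm,
        seg.query_name,
    )


def concatenate(readsets: Iterable[ReadSet]) -> ReadSet:
    """Pool several read sets aligned to the same reference."""
    readsets = [rs for rs in readsets]
    if not readsets:
        raise ValueError("no read sets to concatenate")
    first = readsets[0]
    for rs in readsets[1:]:
        if rs.reference != first.reference or rs.ref_length != first.ref_length:
            raise ValueError("read sets aligned to different references")
    maxw = max(rs.codes.shape[1] for rs in readsets)
    total = sum(rs.n for rs in readsets)
    codes = np.full((total, maxw), PAD, dtype=np.uint8)
    have_quals = all(rs.quals is not None for rs in readsets)
    quals = np.zeros((total, maxw), dtype=np.uint8) if have_quals else None
    offset = 0
    for rs in readsets:
        codes[offset : offset + rs.n, : rs.codes.shape[1]] = rs.codes
        if have_quals:
            quals[offset : offset + rs.n, : rs.codes.shape[1]] = rs.quals
        offset += rs.n
    cat = lambda attr: np.concatenate([getattr(rs, attr) for rs in readsets])
    out = ReadSet(
        first.reference,
        first.ref_length,
        first.circular,
        cat("qstart"),
        cat("qlen"),
        cat("left_clip"),
        cat("right_clip"),
        codes,
        cat("reverse"),
        cat("proper"),
        cat("mate2"),
        quals,
        None,
        first.sample,
        first.ref_codes,
    )
    if all(rs._nm is not None for rs in readsets):
        out.set_nm(np.concatenate([rs._nm for rs in readsets]))
    return out
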