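"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are 0-based, half-open (BED-native) everywhere in the
package; every convention decision about external formats lives in this
module. Candidate binding sites arrive as BED6 (optionally with a TSV of
extra per-instance features), ChIP-seq peaks as ENCODE narrowPeak,
per-base strand-specific DNase I cut counts as a pair of bedGraph tracks
or extracted from read alignments (SAM/BAM).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MotifInstanceSet:
    """Candidate TF binding sites with prior characteristics.

    Each instance is a genomic match to the primary motif; ``features``
    holds the per-instance prior characteristic vector (columns named;
    at minimum a ``motif_score`` column). All instances share the same
    motif length ``L``.
    """

    chrom: np.ndarray          # object array of contig names
    start: np.ndarray          # int64
    end: np.ndarray            # int64
    strand: np.ndarray         # object array of '+'/'-'
    instance_id: np.ndarray    # object array, unique
    features: pd.DataFrame     # n_instances x J, float
    motif_length: int

    def __post_init__(self) -> None:
        widths = self.end - self.start
        if len(widths) and not np.all(widths == self.motif_length):
            raise FormatError("inconsistent motif length among instances")
        if self.features.isna().any().any():
            raise FormatError("feature matrix contains missing values")
        if self.features.shape[1] < 1:
            raise FormatError("at least one prior characteristic required")
        if len(set(self.instance_id)) != len(self.instance_id):
            raise FormatError("instance_ids are not unique")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


@dataclass
class PeakSet:
    """ChIP-seq peaks with their signal values (peak heights)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    signal_value: np.ndarray

    def __post_init__(self) -> None:
        if len(self.start) and not np.all(self.start < self.end):
            raise FormatError("peak with start >= end")

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class CutTrack:
    """Per-contig, per-strand sparse arrays of per-base cut counts.

    Stored as {(contig, strand): {position: count}} dictionaries, giving
    amortised O(1) random access; `window` materialises a dense slice.
    """

    counts: dict = field(default_factory=dict)

    def add(self, contig: str, strand: str, position: int, count: int = 1) -> None:
        if count < 0:
            raise FormatError("negative cut count")
        key = (contig, strand)
        store = self.counts.setdefault(key, {})
        store[position] = store.get(position, 0) + count

    def get(self, contig: str, strand: str, position: int) -> int:
        return self.counts.get((contig, strand), {}).get(position, 0)

    def window(self, contig: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense counts over [start, end) on one strand."""
        out = np.zeros(end - start, dtype=np.int64)
        store = self.counts.get((contig, strand))
        if store is None:
            return out
        if len(store) < (end - start):
            for pos, c in store.items():
                if start <= pos < end:
                    out[pos - start] = c
        else:
            for j in range(start, end):
                c = store.get(j)
                if c:
                    out[j - start] = c
        return out

    def total(self) -> int:
        return sum(sum(s.values()) for s in self.counts.values())


# ---------------------------------------------------------------------------
# Candidate binding sites
# ---------------------------------------------------------------------------

def read_candidate_sites(bed_path, feature_path=None) -> MotifInstanceSet:
    """Read candidate motif instances from BED6, optionally joined with a
    TSV of extra numeric features keyed by instance_id.

    The BED score column becomes the feature ``motif_score`` unless the TSV
    overrides it. Instances are sorted by (chrom, start). All intervals must
    share the same width (the motif length).
    """
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise FormatError(f"line {lineno}: BED6 requires >= 6 columns")
            chrom, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: strand must be + or -")
            rows.append((lineno, chrom, start, end, name, float(score), strand))

    if not rows:
        raise FormatError("empty BED file")

    widths = {r[3] - r[2] for r in rows}
    if len(widths) > 1:
        bad = next(r for r in rows if r[3] - r[2] != rows[0][3] - rows[0][2])
        raise FormatError(
            f"inconsistent motif length: line {bad[0]} has width "
            f"{bad[3] - bad[2]}, expected {rows[0][3] - rows[0][2]}"
        )
    motif_length = widths.pop()

    df = pd.DataFrame(
        [r[1:] for r in rows],
        columns=["chrom", "start", "end", "instance_id", "motif_score", "strand"],
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    features = df[["motif_score"]].astype(float)
    features.index = pd.Index(df["instance_id"])

    if feature_path is not None:
        tsv = pd.read_csv(feature_path, sep="\t", index_col="instance_id")
        missing = set(df["instance_id"]) - set(tsv.index.astype(str))
        if missing:
            raise FormatError(f"instance_ids missing from feature TSV: {sorted(missing)[:5]}")
        tsv = tsv.loc[df["instance_id"]].astype(float)
        for col in tsv.columns:
            features[col] = tsv[col].to_numpy()

    return MotifInstanceSet(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        strand=df["strand"].to_numpy(dtype=object),
        instance_id=df["instance_id"].to_numpy(dtype=object),
        features=features.reset_index(drop=True),
        motif_length=int(motif_length),
    )


# ---------------------------------------------------------------------------
# ChIP-seq peaks and labelling
# ---------------------------------------------------------------------------

def read_peaks(path) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file; signalValue is column 7."""
    chroms, starts, ends, signals = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 10:
                raise FormatError(f"line {lineno}: narrowPeak requires 10 columns")
            chroms.append(parts[0])
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            sig = parts[6]
            signals.append(float("nan") if sig == "." else float(sig))
    return PeakSet(
        chrom=np.asarray(chroms, dtype=object),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        signal_value=np.asarray(signals, dtype=float),
    )


def label_instances(sites: MotifInstanceSet, peaks: PeakSet) -> pd.DataFrame:
    """Classify each motif instance as bound/unbound by ChIP-seq overlap.

    A site is bound iff it overlaps any peak by >= 1 bp (half-open
    semantics). ``peak_height`` is the maximum signalValue over overlapping
    peaks; NaN for unbound sites.

    Returns a DataFrame indexed like the instance set with columns
    ``bound`` (bool) and ``peak_height`` (float).
    """
    trees: dict[str, IntervalTree] = {}
    for c, s, e, v in zip(peaks.chrom, peaks.start, peaks.end, peaks.signal_value):
        trees.setdefault(c, IntervalTree()).addi(int(s), int(e), float(v))

    bound = np.zeros(len(sites), dtype=bool)
    height = np.full(len(sites), np.nan)
    for i, (c, s, e) in enumerate(zip(sites.chrom, sites.start, sites.end)):
        tree = trees.get(c)
        if tree is None:
            continue
        hits = tree.overlap(int(s), int(e))
        if hits:
            bound[i] = True
            height[i] = max(h.data for h in hits)
    return pd.DataFrame(
        {"instance_id": sites.instance_id, "bound": bound, "peak_height": height}
    )


# ---------------------------------------------------------------------------
# Cut tracks: bedGraph and alignments
# ---------------------------------------------------------------------------

def load_cut_track(fwd_path, rev_path) -> CutTrack:
    """Load strand-specific per-base cut counts from two bedGraph files.

    A value v over [a, b) expands to count v at every base in [a, b).
    """
    track = CutTrack()
    for path, strand in ((fwd_path, "+"), (rev_path, "-")):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                chrom, a, b, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if v < 0:
                    raise FormatError(f"{path} line {lineno}: negative value")
                iv = int(round(v))
                if iv == 0:
                    continue
                for pos in range(a, b):
                    track.add(chrom, strand, pos, iv)
    return track


def write_bedgraph(track: CutTrack, fwd_path, rev_path) -> None:
    """Write a CutTrack as two bedGraph files, merging equal-valued runs."""
    for path, strand in ((fwd_path, "+"), (rev_path, "-")):
        with open(path, "w") as fh:
            for (contig, s), store in sorted(track.counts.items()):
                if s != strand:
                    continue
                run_start = run_val = None
                prev = None
                for pos in sorted(store):
                    val = store[pos]
                    if val == 0:
                        continue
                    if run_start is not None and pos == prev + 1 and val == run_val:
                        prev = pos
                        continue
                    if run_start is not None:
                        fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{run_val}\n")
                    run_start, run_val, prev = pos, val, pos
                if run_start is not None:
                    fh.write(f"{contig}\t{run_start}\t{prev + 1}\t{run_val}\n")


def cuts_from_alignments(path, reverse_shift: int = 0) -> CutTrack:
    """Extract per-base DNase I cut counts from aligned reads (SAM/BAM).

    The cut site is the 5' base of the aligned sequence tag: the leftmost
    aligned position for forward-strand reads, the rightmost for
    reverse-strand reads (optionally shifted by ``reverse_shift`` bp).
    Unmapped, secondary, supplementary and duplicate records are skipped.
    """
    import pysam

    track = CutTrack()
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or
                    read.is_supplementary or read.is_duplicate):
                continue
            if read.is_reverse:
                track.add(read.reference_name, "-",
                          read.reference_end - 1 + reverse_shift)
            else:
                track.add(read.reference_name, "+", read.reference_start)
    return track


# ---------------------------------------------------------------------------
# Model and posterior persistence
# ---------------------------------------------------------------------------

def write_posteriors(sites: MotifInstanceSet, posterior: np.ndarray, path) -> None:
    """Write per-instance posterior probabilities as TSV.

    One row per instance: instance_id, coordinates, p_i (probability of
    being bound in any mode), then one column per state.
    """
    posterior = np.asarray(posterior, dtype=float)
    if posterior.shape[0] != len(sites):
        raise ValueError("posterior rows do not match number of instances")
    n_states = posterior.shape[1]
    df = pd.DataFrame({
        "instance_id": sites.instance_id,
        "chrom": sites.chrom,
        "start": sites.start,
        "end": sites.end,
        "strand": sites.strand,
        "p_bound": 1.0 - posterior[:, 0],
    })
    for k in range(n_states):
        df[f"state_{k}"] = posterior[:, k]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def save_model(params, path) -> None:
    """Serialise fitted model parameters as JSON (round-trip exact)."""
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)


def load_model(path):
    """Load model parameters saved by :func:`save_model`."""
    from footmix.mixture_model import ModelParams

    with open(path) as fh:
        return ModelParams.from_dict(json.load(fh))
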