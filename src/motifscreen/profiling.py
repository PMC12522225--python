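"""End-motif extraction from aligned cfDNA fragments.

A sequenced plasma fragment has two ends; under the dominant fragmentomics
convention each strand's 5' terminal 4-mer is counted, i.e. for a fragment
spanning reference interval [s, e):

* left terminus: the reference 4-mer ``ref[s:s+4]`` read on the forward
  strand;
* right terminus: the reverse complement of ``ref[e-4:e]`` (the 5' end of
  the reverse strand).

Motifs are taken from the reference rather than read bases, so sequencing
errors do not perturb the profile; a soft-clipped terminus disqualifies
that end.  Terminal windows containing N contribute nothing.

Each properly paired fragment is counted once per end regardless of which
mate is traversed: the forward mate of a proper pair carries the left
terminus, the reverse mate the right terminus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .motifs import MOTIFS_4MER
from .simulate import revcomp

_MOTIF_TO_IDX = {m: i for i, m in enumerate(MOTIFS_4MER)}

END_CONVENTIONS = (
    "five_prime_both_ends",
    "five_prime_left_only",
    "three_prime_both_ends",
)


@dataclass
class ProfilerConfig:
    """Filters and conventions for fragment-end profiling.

    ``min_mapping_quality`` (default 30) and the fragment-length window
    (default 50-500 bp, spanning the mono- to tri-nucleosomal cfDNA range)
    gate which fragments are counted; ``min_usable_fragments`` (default
    1000) marks samples whose profile is too shallow to normalise.
    """

    end_convention: str = "five_prime_both_ends"
    min_mapping_quality: int = 30
    min_fragment_length: int = 50
    max_fragment_length: int = 500
    min_usable_fragments: int = 1000

    def __post_init__(self) -> None:
        if self.end_convention not in END_CONVENTIONS:
            raise ValueError(f"unknown end convention {self.end_convention!r}")
        if not 0 < self.min_fragment_length < self.max_fragment_length:
            raise ValueError("fragment length bounds must satisfy 0 < min < max")


@dataclass
class SampleProfile:
    """One sample's motif counts plus usability bookkeeping."""

    counts: pd.Series
    usable_fragments: int
    usable: bool
    ends_per_fragment: int  # 1 or 2 depending on convention


def _terminal_motifs(ref_seq: str, start: int, end: int, convention: str):
    """The motif(s) a fragment [start, end) contributes, as a list of
    (which_end, motif) pairs; ``ref_seq`` is the full contig sequence."""
    left = ref_seq[start : start + 4].upper()
    right = ref_seq[end - 4 : end].upper()
    if convention == "five_prime_both_ends":
        return [("left", left), ("right", revcomp(right))]
    if convention == "five_prime_left_only":
        return [("left", left)]
    # three_prime_both_ends: forward strand 3' end is the right terminus
    # read forward; reverse strand 3' end is revcomp of the left terminus
    return [("right", right), ("left", revcomp(left))]


def extract_end_motifs(
    alignment_path: str | Path,
    reference_path: str | Path,
    config: ProfilerConfig | None = None,
) -> SampleProfile:
    """Profile one sample's alignment file into a 256-motif count row.

    Iterates properly paired, primary, non-duplicate records with mapping
    quality and inferred fragment length within the configured bounds.
    Under the default both-ends convention the forward mate contributes the
    fragment's left-terminus motif and the reverse mate the right-terminus
    motif, so each fragment end is counted exactly once.

    ``usable_fragments`` counts fragments contributing at least one end.
    """
    config = config or ProfilerConfig()
    alignment_path = Path(alignment_path)
    if alignment_path.suffix == ".bam":
        idx = alignment_path.with_suffix(".bam.bai")
        idx2 = alignment_path.with_suffix(".bai")
        if not idx.exists() and not idx2.exists():
            raise FileNotFoundError(f"missing index for {alignment_path}")
    counts = np.zeros(len(MOTIFS_4MER), dtype=np.int64)
    contributing: set[str] = set()  # fragments contributing >= 1 end

    mode = "rb" if alignment_path.suffix == ".bam" else "r"
    with pysam.FastaFile(str(reference_path)) as fasta:
        ref_cache: dict[str, str] = {}
        with pysam.AlignmentFile(str(alignment_path), mode) as bam:
            for read in bam:
                if (
                    not read.is_proper_pair
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.is_unmapped
                    or read.is_qcfail
                ):
                    continue
                if read.mapping_quality < config.min_mapping_quality:
                    continue
                tlen = read.template_length
                if not (
                    config.min_fragment_length <= abs(tlen) <= config.max_fragment_length
                ):
                    continue
                # the forward mate (tlen > 0) owns the fragment's left end,
                # the reverse mate (tlen < 0) its right end
                if tlen > 0 and not read.is_reverse:
                    which = "left"
                    start = read.reference_start
                    end = start + tlen
                elif tlen < 0 and read.is_reverse:
                    which = "right"
                    end = read.reference_end
                    start = end + tlen  # tlen negative
                else:
                    continue
                cigar = read.cigartuples or []
                # a soft/hard-clipped terminus means the fragment boundary
                # is not the alignment boundary: disqualify that end
                if which == "left" and cigar and cigar[0][0] in (4, 5):
                    continue
                if which == "right" and cigar and cigar[-1][0] in (4, 5):
                    continue
                contig = read.reference_name
                if contig not in ref_cache:
                    ref_cache[contig] = fasta.fetch(contig)
                ref_seq = ref_cache[contig]
                if start < 0 or end > len(ref_seq):
                    continue
                for end_name, motif in _terminal_motifs(
                    ref_seq, start, end, config.end_convention
                ):
                    if end_name != which:
                        continue
                    i = _MOTIF_TO_IDX.get(motif)
                    if i is not None:
                        counts[i] += 1
                        contributing.add(read.query_name)

    per_frag = 1 if config.end_convention == "five_prime_left_only" else 2
    usable_fragments = len(contributing)
    series = pd.Series(counts, index=list(MOTIFS_4MER))
    return SampleProfile(
        counts=series,
        usable_fragments=usable_fragments,
        usable=usable_fragments >= config.min_usable_fragments,
        ends_per_fragment=per_frag,
    )


def profile_cohort(
    alignments: dict[str, str | Path],
    reference_path: str | Path,
    config: ProfilerConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile many samples into a counts matrix.

    Parameters
    ----------
    alignments : mapping sample_id -> alignment file path

    Returns
    -------
    counts : DataFrame, samples x 256 motifs
    info : DataFrame with usable_fragments and the usability flag per sample
    """
    config = config or ProfilerConfig()
    rows, infos = [], []
    for sample_id, path in alignments.items():
        profile = extract_end_motifs(path, reference_path, config)
        rows.append(profile.counts.rename(sample_id))
        infos.append(
            {
                "sample_id": sample_id,
                "usable_fragments": profile.usable_fragments,
                "usable": profile.usable,
            }
        )
    counts = pd.DataFrame(rows)
    counts.index.name = "sample_id"
    info = pd.DataFrame(infos).set_index("sample_id")
    return counts, info


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    if list(frame.columns) != list(MOTIFS_4MER):
        raise ValueError(f"{path}: columns are not the 256 lexicographic 4-mers")
    return frame
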