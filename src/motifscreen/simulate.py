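"""Synthetic plasma-cohort generator.

No public cfDNA data accompany the screening study this package models, so
every downstream stage is exercised on simulated cohorts with the same
statistical structure the analysis assumes:

* a case/control cohort with group structure {control, ESPL, ESCC} and
  subgroups {Health, Benign, LGIN, HGIN, stage I-IV}, where ESPL denotes
  esophageal squamous precancerous lesions (LGIN/HGIN);
* per-sample 4-mer end-motif counts drawn Dirichlet-multinomial around a
  fixed baseline composition, with a planted subset of motifs shifted up
  (default 75) or down (default 128) in cases on the log scale, the shift
  growing with disease severity;
* a nine-marker tumour-protein panel drawn log-normal with multiplicative
  group shifts (CEA, Cyfra21-1, PG I, PG II elevated in cases by default),
  plus the derived pepsinogen ratio PGR = PG I / PG II;
* optional aligned paired-end fragment files whose terminal 4-mers
  reproduce a given count matrix exactly, for round-trip testing of the
  alignment profiler.

Everything is deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import MOTIFS_4MER, motif_index

SUBGROUPS = (
    "Health",
    "Benign",
    "LGIN",
    "HGIN",
    "StageI",
    "StageII",
    "StageIII",
    "StageIV",
)

#: fixed clinical mapping: intraepithelial neoplasia grades form the
#: precancerous (ESPL) group, invasive stages the ESCC group
SUBGROUP_TO_GROUP = {
    "Health": "control",
    "Benign": "control",
    "LGIN": "ESPL",
    "HGIN": "ESPL",
    "StageI": "ESCC",
    "StageII": "ESCC",
    "StageIII": "ESCC",
    "StageIV": "ESCC",
}

CASE_SUBGROUP_ORDER = ("LGIN", "HGIN", "StageI", "StageII", "StageIII", "StageIV")

PROTEIN_MARKERS = (
    "AFP",
    "CA19-9",
    "CA24-2",
    "CA72-4",
    "CEA",
    "Cyfra21-1",
    "SCC",
    "PG I",
    "PG II",
)

#: enrolment pattern of the modelled screening study (491 participants)
DEFAULT_N_PER_SUBGROUP = {
    "Health": 29,
    "Benign": 172,
    "LGIN": 46,
    "HGIN": 45,
    "StageI": 124,
    "StageII": 23,
    "StageIII": 35,
    "StageIV": 17,
}

DEFAULT_SEVERITY = {
    "LGIN": 0.5,
    "HGIN": 0.6,
    "StageI": 0.7,
    "StageII": 0.8,
    "StageIII": 0.9,
    "StageIV": 1.0,
}

# typical plasma concentrations (log-scale location = log of the median);
# sigma is the log-scale sd.  Shifts >1 elevate the marker in ESPL/ESCC;
# PG I and PG II shift unequally so their ratio (PGR) is itself shifted.
DEFAULT_PROTEIN_PARAMS = {
    "AFP": {"loc": np.log(3.0), "sigma": 0.5, "shift": {"control": 1.0, "ESPL": 1.0, "ESCC": 1.0}},
    "CA19-9": {"loc": np.log(10.0), "sigma": 0.6, "shift": {"control": 1.0, "ESPL": 1.0, "ESCC": 1.0}},
    "CA24-2": {"loc": np.log(5.0), "sigma": 0.6, "shift": {"control": 1.0, "ESPL": 1.0, "ESCC": 1.0}},
    "CA72-4": {"loc": np.log(2.0), "sigma": 0.6, "shift": {"control": 1.0, "ESPL": 1.0, "ESCC": 1.0}},
    "CEA": {"loc": np.log(2.0), "sigma": 0.5, "shift": {"control": 1.0, "ESPL": 1.3, "ESCC": 1.5}},
    "Cyfra21-1": {"loc": np.log(2.0), "sigma": 0.5, "shift": {"control": 1.0, "ESPL": 1.3, "ESCC": 1.5}},
    "SCC": {"loc": np.log(1.0), "sigma": 0.5, "shift": {"control": 1.0, "ESPL": 1.0, "ESCC": 1.0}},
    "PG I": {"loc": np.log(50.0), "sigma": 0.5, "shift": {"control": 1.0, "ESPL": 1.4, "ESCC": 1.6}},
    "PG II": {"loc": np.log(8.0), "sigma": 0.5, "shift": {"control": 1.0, "ESPL": 1.15, "ESCC": 1.3}},
}

# frozen internal seed for the baseline motif composition: the "ground
# truth" composition is identical across installs and independent of the
# user-facing simulation seed
_BASELINE_SEED = 715517
_BASELINE_DIRICHLET_ALPHA = 20.0


def baseline_motif_probs() -> np.ndarray:
    """The fixed 256-motif baseline composition (sums to 1).

    Drawn once from a symmetric Dirichlet with a frozen internal seed, so
    planted effects are always defined relative to the same baseline.
    """
    rng = np.random.default_rng(_BASELINE_SEED)
    return rng.dirichlet(np.full(len(MOTIFS_4MER), _BASELINE_DIRICHLET_ALPHA))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_per_subgroup : dict
        Samples per clinical subgroup; defaults to the modelled study's
        enrolment (491 participants).
    n_up_motifs, n_down_motifs : int
        Sizes of the planted up-/down-shifted motif sets (75 / 128 by
        default); disjoint subsets of the 256 4-mers.
    effect_delta : float
        Log-scale shift applied to planted motif probabilities in cases.
    severity_scaling : dict
        Multiplier in [0, 1] on ``effect_delta`` per case subgroup,
        non-decreasing from LGIN to stage IV.
    dirichlet_concentration : float
        Between-sample variability of the motif composition (higher =
        tighter around the subgroup mean).
    fragments_mean, fragments_dispersion : float
        Negative-binomial mean and shape for per-sample fragment totals
        (desk-scale default 50,000 fragments).
    protein_params : dict
        Per-marker log-normal location/scale and per-group multiplicative
        shift.
    seed : int
        Root seed for all randomness in the generator.
    """

    n_per_subgroup: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_SUBGROUP))
    n_up_motifs: int = 75
    n_down_motifs: int = 128
    effect_delta: float = 0.3
    severity_scaling: dict = field(default_factory=lambda: dict(DEFAULT_SEVERITY))
    dirichlet_concentration: float = 2000.0
    fragments_mean: float = 50_000.0
    fragments_dispersion: float = 10.0
    protein_params: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROTEIN_PARAMS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_subgroup) - set(SUBGROUPS)
        if unknown:
            raise ValueError(f"unknown subgroups: {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_subgroup.values()):
            raise ValueError("subgroup counts must be >= 0")
        if self.n_up_motifs + self.n_down_motifs > len(MOTIFS_4MER):
            raise ValueError("planted up+down motif sets exceed 256 motifs")
        if self.n_up_motifs < 0 or self.n_down_motifs < 0:
            raise ValueError("planted set sizes must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.fragments_mean <= 0 or self.fragments_dispersion <= 0:
            raise ValueError("fragment total parameters must be > 0")
        sev = [self.severity_scaling.get(s, 0.0) for s in CASE_SUBGROUP_ORDER]
        if any(not 0 <= v <= 1 for v in sev):
            raise ValueError("severity multipliers must lie in [0, 1]")
        if any(b < a for a, b in zip(sev, sev[1:])):
            raise ValueError(
                "severity multipliers must be non-decreasing from LGIN to stage IV"
            )
        for marker in PROTEIN_MARKERS:
            if marker not in self.protein_params:
                raise ValueError(f"protein_params missing marker {marker!r}")
            if self.protein_params[marker]["sigma"] <= 0:
                raise ValueError(f"protein sigma must be > 0 for {marker!r}")
            if any(s <= 0 for s in self.protein_params[marker]["shift"].values()):
                raise ValueError(f"protein shifts must be > 0 for {marker!r}")

def _stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    # stage-scoped streams derived from the root seed, so each generator
    # output is independently reproducible
    table = {"metadata": 1, "motifs": 2, "proteins": 3, "fragments": 4}
    return np.random.default_rng([int(config.seed), table[stage]])


def generate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the cohort table: one row per participant.

    Group is derived from subgroup by the fixed clinical mapping; age, sex,
    smoking and drinking are drawn from fixed marginals comparable across
    subgroups (the split-comparability report should find no differences).
    """
    total = sum(config.n_per_subgroup.values())
    if total == 0:
        raise ValueError("empty cohort: all subgroup counts are zero")
    rng = _stage_rng(config, "metadata")
    rows = []
    for subgroup in SUBGROUPS:
        n = int(config.n_per_subgroup.get(subgroup, 0))
        for _ in range(n):
            rows.append(
                {
                    "subgroup": subgroup,
                    "group": SUBGROUP_TO_GROUP[subgroup],
                    "age": int(np.clip(round(rng.normal(60.0, 9.0)), 30, 85)),
                    "sex": "male" if rng.random() < 0.64 else "female",
                    "smoking": rng.choice(
                        ["smoker", "non-smoker", "unknown"], p=[0.25, 0.65, 0.10]
                    ),
                    "drinking": rng.choice(
                        ["drinker", "non-drinker", "unknown"], p=[0.28, 0.62, 0.10]
                    ),
                }
            )
    meta = pd.DataFrame(rows)
    meta.insert(0, "sample_id", [f"S{i:04d}" for i in range(len(meta))])
    meta["split"] = ""
    return meta


def _subgroup_mean_probs(config: SimulationConfig, up: np.ndarray, down: np.ndarray):
    """Per-subgroup mean motif composition: baseline perturbed by
    exp(+/- severity*delta) on the planted sets, renormalised."""
    base = baseline_motif_probs()
    means = {}
    for subgroup in SUBGROUPS:
        severity = config.severity_scaling.get(subgroup, 0.0)
        if SUBGROUP_TO_GROUP[subgroup] == "control":
            severity = 0.0
        p = base.copy()
        with np.errstate(over="ignore", under="ignore"):
            p[up] *= np.exp(severity * config.effect_delta)
            p[down] *= np.exp(-severity * config.effect_delta)
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            raise ValueError("planted effect degenerates the motif composition")
        means[subgroup] = p / p.sum()
    return means


def generate_motif_counts(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-sample motif counts and return planted ground truth.

    For each sample: total fragments N_s ~ negative binomial; composition
    p_s ~ Dirichlet(concentration * subgroup mean); counts ~
    Multinomial(N_s, p_s), so each row sums exactly to its drawn N_s.

    Returns
    -------
    counts : DataFrame, samples x 256 motifs
    ground_truth : dict with ``up_motifs`` / ``down_motifs`` (names) and the
        matching index arrays.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rng = _stage_rng(config, "motifs")
    planted = rng.choice(
        len(MOTIFS_4MER), size=config.n_up_motifs + config.n_down_motifs, replace=False
    )
    up = np.sort(planted[: config.n_up_motifs])
    down = np.sort(planted[config.n_up_motifs :])
    means = _subgroup_mean_probs(config, up, down)

    k = config.fragments_dispersion
    m = config.fragments_mean
    totals = rng.negative_binomial(k, k / (k + m), size=len(cohort))
    counts = np.zeros((len(cohort), len(MOTIFS_4MER)), dtype=np.int64)
    for i, (subgroup, n_s) in enumerate(zip(cohort["subgroup"], totals)):
        alpha = config.dirichlet_concentration * means[subgroup]
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(int(n_s), p)
    frame = pd.DataFrame(
        counts, index=list(cohort["sample_id"]), columns=list(MOTIFS_4MER)
    )
    frame.index.name = "sample_id"
    ground_truth = {
        "up_motifs": [MOTIFS_4MER[i] for i in up],
        "down_motifs": [MOTIFS_4MER[i] for i in down],
        "up_index": up.tolist(),
        "down_index": down.tolist(),
    }
    return frame, ground_truth


def generate_protein_panel(
    cohort: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate the nine-marker protein panel plus the derived PGR column.

    Each marker is log-normal with a group-specific multiplicative shift;
    all values are strictly positive by construction.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rng = _stage_rng(config, "proteins")
    data = {}
    groups = cohort["group"].to_numpy()
    for marker in PROTEIN_MARKERS:
        params = config.protein_params[marker]
        shift = np.array([params["shift"].get(g, 1.0) for g in groups])
        draws = rng.lognormal(mean=params["loc"], sigma=params["sigma"], size=len(cohort))
        data[marker] = draws * shift
    table = pd.DataFrame(data, index=list(cohort["sample_id"]))
    table["PGR"] = table["PG I"] / table["PG II"]
    table.index.name = "sample_id"
    return table


# ---------------------------------------------------------------------------
# fragment-level output for round-tripping the alignment profiler


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fragments(
    cohort: pd.DataFrame,
    counts: pd.DataFrame,
    out_dir: str | Path,
    reference_length: int = 12_000_000,  # covers all 256^2 end-motif pairs
    fragment_length: int = 166,
    read_length: int = 50,
    seed: int = 0,
) -> dict:
    """Emit sorted, indexed paired-end alignments realising ``counts``.

    Each count unit is one end-motif observation.  Observations are paired
    two per fragment (left terminus, right terminus); when a sample has an
    odd number of observations the last fragment's right terminal window is
    written as NNNN on the reference, which the profiler skips, so
    profiling the emitted files under the default both-ends convention
    returns ``counts`` exactly.

    A compact synthetic reference is built containing one segment per
    distinct (left motif, right motif) pair actually needed; all fragments
    with that pair map to that segment.  Writes per-sample BAM + index, a
    shared reference FASTA + index, and a bookkeeping JSON with the
    ground-truth counts.

    Returns a manifest dict with file paths.
    """
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fragment_length < 2 * 4:
        raise ValueError("fragment_length too short to carry two end motifs")
    read_length = min(read_length, fragment_length)
    rng = np.random.default_rng([int(seed), 4])

    # pair observations per sample
    per_sample_pairs: dict[str, list[tuple[int, int]]] = {}
    needed_keys: set[tuple[int, int]] = set()
    for sample_id in counts.index:
        row = counts.loc[sample_id].to_numpy()
        obs = np.repeat(np.arange(len(MOTIFS_4MER)), row)
        rng.shuffle(obs)
        pairs = []
        for j in range(0, len(obs) - 1, 2):
            pairs.append((int(obs[j]), int(obs[j + 1])))
        if len(obs) % 2 == 1:
            pairs.append((int(obs[-1]), -1))  # -1: unreadable right end
        per_sample_pairs[sample_id] = pairs
        needed_keys.update(pairs)

    # build the reference: one fragment-length segment per distinct pair
    keys = sorted(needed_keys)
    spacer_len = fragment_length - 8
    total_len = len(keys) * fragment_length
    if total_len > reference_length:
        raise ValueError(
            f"reference_length {reference_length} too short: need {total_len} bp "
            f"for {len(keys)} distinct end-motif pairs"
        )
    segments = []
    positions: dict[tuple[int, int], int] = {}
    pos = 0
    bases = np.array(list("ACGT"))
    if not keys:
        # all-zero matrix: still emit a valid non-empty reference so the
        # FASTA/BAM headers are well formed
        segments.append("".join(rng.choice(bases, size=fragment_length)))
        pos = fragment_length
    for left, right in keys:
        spacer = "".join(rng.choice(bases, size=spacer_len))
        right_part = "NNNN" if right == -1 else revcomp(MOTIFS_4MER[right])
        segments.append(MOTIFS_4MER[left] + spacer + right_part)
        positions[(left, right)] = pos
        pos += fragment_length
    reference = "".join(segments)

    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(">chrS\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")
    pysam.faidx(str(fasta_path))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chrS", "LN": len(reference)}],
    }
    bam_paths = {}
    for sample_id in counts.index:
        bam_path = out_dir / f"{sample_id}.bam"
        pairs = per_sample_pairs[sample_id]
        # group fragments by segment so output is coordinate sorted
        by_pos: dict[int, int] = {}
        for key in pairs:
            p = positions[key]
            by_pos[p] = by_pos.get(p, 0) + 1
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
            frag_no = 0
            for p in sorted(by_pos):
                records = []
                for _ in range(by_pos[p]):
                    name = f"{sample_id}:frag{frag_no}"
                    frag_no += 1
                    r1 = pysam.AlignedSegment(bam.header)
                    r1.query_name = name
                    r1.flag = 99  # paired, proper, mate reverse, first
                    r1.reference_id = 0
                    r1.reference_start = p
                    r1.mapping_quality = 60
                    r1.cigarstring = f"{read_length}M"
                    r1.query_sequence = reference[p : p + read_length]
                    r1.next_reference_id = 0
                    r1.next_reference_start = p + fragment_length - read_length
                    r1.template_length = fragment_length
                    r2 = pysam.AlignedSegment(bam.header)
                    r2.query_name = name
                    r2.flag = 147  # paired, proper, reverse, second
                    r2.reference_id = 0
                    r2.reference_start = p + fragment_length - read_length
                    r2.mapping_quality = 60
                    r2.cigarstring = f"{read_length}M"
                    r2.query_sequence = reference[
                        p + fragment_length - read_length : p + fragment_length
                    ]
                    r2.next_reference_id = 0
                    r2.next_reference_start = p
                    r2.template_length = -fragment_length
                    records.append((r1, r2))
                for r1, _ in records:
                    bam.write(r1)
                for _, r2 in records:
                    bam.write(r2)
        # mates at p and p+L-rl interleave across segments only if segments
        # overlap, which they never do; within a segment r1 precedes r2
        # unless read_length == fragment_length (then positions tie)
        pysam.index(str(bam_path))
        bam_paths[sample_id] = str(bam_path)

    truth_path = out_dir / "ground_truth_counts.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "motifs": list(MOTIFS_4MER),
                "counts": {s: counts.loc[s].tolist() for s in counts.index},
                "fragment_length": fragment_length,
            },
            fh,
        )
    return {
        "reference": str(fasta_path),
        "bams": bam_paths,
        "ground_truth": str(truth_path),
    }
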