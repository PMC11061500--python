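"""Study designs, pseudo-observed datasets, and planted-truth fixtures.

This module is the stand-in for the deposited raw data: it reproduces the
two study designs (a 118-individual / 338-SNP "cluster" design spanning the
whole north/south range split, and a 27-individual / 181-SNP "population"
design restricted to one region per geographic cluster), generates
pseudo-observed datasets (PODs) with known scenario and parameters for
calibration, and builds fixtures with planted ground truth for the filter
cascade and the chloroplast direction caller.  Every generator emits a
machine-readable truth record next to the data.

Per-deme sample splits are defaults chosen to match the published group
totals (81 PAM, 36 hybrids, 1 HIM in the cluster design); the exact per-deme
counts of the deposited matrices are not printed and the splits are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalsim import SampleConfig, simulate_snp_dataset
from .genotypes import MISSING, SnpDataset, write_dart_csv
from .scenarios import ParameterVector, PriorSpec, build_scenario, draw_parameters

__all__ = [
    "StudyDesign",
    "study_design",
    "make_pod",
    "make_dart_fixture",
    "make_cpdna_fixture",
    "DEFAULT_DIAG_SPEC",
]

#: default per-deme diploid sample sizes for the two study designs
_DESIGNS = {
    "cluster": (
        {"PAM_N": 41, "PAM_S": 40, "HYB_N": 18, "HYB_S": 18, "HIM": 1}, 338),
    "population": (
        {"PAM_N": 7, "PAM_S": 6, "HYB_N": 7, "HYB_S": 6, "HIM": 1}, 181),
}


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: per-deme sizes, locus count, and MAF threshold."""

    name: str
    sample_sizes: dict[str, int]
    n_loci: int
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        expected_totals = {"cluster": 118, "population": 27}
        if self.name in expected_totals:
            total = sum(self.sample_sizes.values())
            if total != expected_totals[self.name]:
                raise ValueError(
                    f"{self.name} design must total {expected_totals[self.name]} "
                    f"individuals, got {total}"
                )

    @property
    def sample_config(self) -> SampleConfig:
        return SampleConfig(dict(self.sample_sizes))


def study_design(name: str, sample_sizes: dict[str, int] | None = None,
                 n_loci: int | None = None, min_maf: float = 0.05) -> StudyDesign:
    """Return a named study design, optionally overriding sizes or loci.

    ``cluster``: 118 individuals (81 PAM in two geographic groups, 36
    hybrids in two groups, 1 HIM) at 338 SNPs.  ``population``: 27
    individuals (one region per geographic cluster) at 181 SNPs.  Overrides
    must keep the named design's total individual count.
    """
    if name not in _DESIGNS:
        raise ValueError(f"unknown design {name!r}; choose from {sorted(_DESIGNS)}")
    sizes, loci = _DESIGNS[name]
    return StudyDesign(
        name,
        dict(sample_sizes) if sample_sizes is not None else dict(sizes),
        int(n_loci) if n_loci is not None else loci,
        min_maf,
    )


def make_pod(
    scenario_id: int,
    design: StudyDesign,
    rng,
    theta: ParameterVector | None = None,
    prior: PriorSpec | None = None,
) -> tuple[SnpDataset, dict]:
    """Simulate a pseudo-observed dataset with a truth record.

    Either a fixed parameter vector ``theta`` or a prior to draw one from
    must be supplied.  The truth record stores the scenario id and the flat
    parameter dictionary for recovery scoring.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    prior = prior or PriorSpec()
    if theta is None:
        theta = draw_parameters(prior, scenario_id, rng)
    scn = build_scenario(scenario_id, theta, prior)
    ds = simulate_snp_dataset(scn, design.sample_config, design.n_loci, design.min_maf, rng)
    truth = {"scenario_id": int(scenario_id), "design": design.name,
             "params": theta.as_flat_dict()}
    return ds, truth


# ---------------------------------------------------------------------------
# Filter-cascade fixture with planted expected counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DartFixturePlan:
    """How many loci to plant in each failure category (all disjoint)."""

    n_clean: int = 10
    n_low_reproducibility: int = 2
    n_low_call_rate: int = 3
    n_monomorphic: int = 2
    n_clone_pairs: int = 2  # pairs sharing a clone_id; thinning keeps one each
    n_group_monomorphic: int = 2  # fixed within group B, segregating in group A
    n_low_maf: int = 2  # pooled MAF below 0.05
    n_individuals_per_group: int = 12
    groups: tuple[str, str] = ("PAM", "HYB")


def _clean_locus(rng: np.random.Generator, n_per_group: int) -> np.ndarray:
    """Dosage column polymorphic within both groups with pooled MAF >= 0.1."""
    n = 2 * n_per_group
    while True:
        col = rng.integers(0, 3, size=n).astype(np.int8)
        halves = (col[:n_per_group], col[n_per_group:])
        ok = all(0 < h.sum() < 2 * h.size for h in halves)
        p = col.sum() / (2 * n)
        if ok and 0.1 <= p <= 0.9:
            return col


def make_dart_fixture(
    rng, plan: DartFixturePlan | None = None, csv_path=None
) -> tuple[SnpDataset, dict]:
    """Build a dataset with known numbers of loci failing each filter.

    Returns the dataset (optionally also written as a DArT-style CSV) and a
    truth record with the expected locus count after each cascade step when
    filtered with thresholds (reproducibility 1.0, locus call rate 1.0,
    individual call rate 1.0), monomorphic removal, clone thinning, strict
    within-group polymorphism over both groups, and MAF 0.05.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    plan = plan or DartFixturePlan()
    npg = plan.n_individuals_per_group
    n_ind = 2 * npg
    ga, gb = plan.groups

    cols: list[np.ndarray] = []
    meta: list[tuple[str, float]] = []  # (category, reproducibility)

    def add(cat: str, col: np.ndarray, repro: float = 1.0, clone: str | None = None):
        cols.append(col)
        meta.append((cat, repro, clone))

    for _ in range(plan.n_clean):
        add("clean", _clean_locus(rng, npg))
    for _ in range(plan.n_low_reproducibility):
        add("low_repro", _clean_locus(rng, npg), repro=0.95)
    for _ in range(plan.n_low_call_rate):
        col = _clean_locus(rng, npg)
        col[rng.integers(n_ind)] = MISSING
        add("low_call_rate", col)
    for _ in range(plan.n_monomorphic):
        add("monomorphic", np.zeros(n_ind, np.int8))
    for k in range(plan.n_clone_pairs):
        clone = f"dupclone{k:03d}"
        add("clone_pair", _clean_locus(rng, npg), clone=clone)
        add("clone_pair", _clean_locus(rng, npg), clone=clone)
    for _ in range(plan.n_group_monomorphic):
        # segregates in group A (pooled MAF kept above 0.05), fixed in group B
        while True:
            half = rng.integers(0, 3, size=npg).astype(np.int8)
            if 3 <= half.sum() <= 2 * npg - 3:
                break
        add("group_monomorphic", np.concatenate([half, np.zeros(npg, np.int8)]))
    for _ in range(plan.n_low_maf):
        # one alt copy in each group: pooled MAF = 2 / (4 * npg) < 0.05 for npg >= 11
        col = np.zeros(n_ind, np.int8)
        col[rng.integers(npg)] = 1
        col[npg + rng.integers(npg)] = 1
        add("low_maf", col)

    order = rng.permutation(len(cols))
    dosages = np.stack([cols[i] for i in order], axis=1)
    categories = [meta[i][0] for i in order]
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j:04d}" for j in range(len(order))],
            "clone_id": [meta[i][2] or f"C{j:04d}" for j, i in enumerate(order)],
            "reproducibility": [meta[i][1] for i in order],
            "allele_ref": "A",
            "allele_alt": "G",
        }
    )
    individuals = pd.DataFrame(
        {
            "individual_id": [f"{g}_{k:03d}" for g in (ga, gb) for k in range(npg)],
            "group_label": [g for g in (ga, gb) for _ in range(npg)],
        }
    )
    ds = SnpDataset(individuals, loci, dosages)

    n_total = len(cols)
    after_repro = n_total - plan.n_low_reproducibility
    after_cr = after_repro - plan.n_low_call_rate
    after_ind = after_cr  # all missing cells removed with their loci
    after_mono = after_ind - plan.n_monomorphic
    after_thin = after_mono - plan.n_clone_pairs
    after_group = after_thin - plan.n_group_monomorphic
    after_maf = after_group - plan.n_low_maf
    truth = {
        "categories": categories,
        "groups": [ga, gb],
        "n_loci": n_total,
        "expected_after": {
            "reproducibility": after_repro,
            "locus_call_rate": after_cr,
            "individual_call_rate": after_ind,
            "monomorphic": after_mono,
            "thin_secondary": after_thin,
            "group_polymorphism_strict": after_group,
            "group_polymorphism_weak": after_thin,  # planted loci segregate in A
            "maf": after_maf,
        },
        "expected_individuals": n_ind,
    }
    if csv_path is not None:
        write_dart_csv(ds, csv_path)
    return ds, truth


# ---------------------------------------------------------------------------
# Chloroplast haplotype fixture
# ---------------------------------------------------------------------------

#: four diagnostic substitutions plus a 4 bp and a 6 bp indel; the 6 bp
#: event is an insertion carried by the PAM class only.
DEFAULT_DIAG_SPEC = {"n_snps": 4, "indel_lengths": (4, 6), "indel_present_in": ("B", "A")}


@dataclass(frozen=True)
class CpdnaFixture:
    """Aligned sequences plus planted truth for the direction caller."""

    sequences: dict[str, str]
    class_a_ids: list[str]  # PAM-class parental accessions
    class_b_ids: list[str]  # HIM-class parental accessions
    hybrid_ids: list[str]
    truth: dict = field(repr=False)


def make_cpdna_fixture(
    rng,
    n_pam: int = 12,
    n_him: int = 1,
    n_hyb_himtype: int = 20,
    n_hyb_pamtype: int = 2,
    diag_spec: dict | None = None,
    length: int = 926,
    n_noise_sites: int = 0,
    fasta_path=None,
) -> CpdnaFixture:
    """Generate an aligned haplotype panel with planted diagnostic differences.

    The alignment (default length 926, the length of the intergenic-spacer
    marker) carries ``n_snps`` fixed substitutions between the two parental
    classes and one indel event per entry of ``indel_lengths`` (a run of
    gap columns in the class that lacks the insertion).  Hybrids copy one
    parental haplotype exactly — their planted maternal class is the truth —
    and optional noise sites vary within a class without being diagnostic.
    PAM-maternal hybrids are placed in distinct localities; HIM-maternal
    hybrids are spread over a handful of localities.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    spec = dict(DEFAULT_DIAG_SPEC, **(diag_spec or {}))
    n_snps = spec["n_snps"]
    indel_lengths = tuple(spec["indel_lengths"])
    indel_present_in = tuple(spec["indel_present_in"])
    if len(indel_present_in) != len(indel_lengths):
        raise ValueError("indel_present_in must match indel_lengths")

    bases = np.array(list("ACGT"))
    backbone = bases[rng.integers(0, 4, size=length)]

    # choose non-adjacent diagnostic columns / runs
    needed = n_snps + sum(indel_lengths) + n_noise_sites
    if needed + 10 > length:
        raise ValueError("alignment too short for the requested diagnostic events")
    taken = np.zeros(length, bool)

    def claim(run: int) -> int:
        while True:
            start = int(rng.integers(1, length - run - 1))
            if not taken[start - 1: start + run + 1].any():
                taken[start: start + run] = True
                return start

    snp_cols = sorted(claim(1) for _ in range(n_snps))
    indel_starts = [claim(ln) for ln in indel_lengths]
    noise_cols = [claim(1) for _ in range(n_noise_sites)]

    seq_a = backbone.copy()  # PAM class
    seq_b = backbone.copy()  # HIM class
    snp_alleles = []
    for c in snp_cols:
        alt = rng.choice([b for b in "ACGT" if b != seq_a[c]])
        seq_b[c] = alt
        snp_alleles.append((c, str(seq_a[c]), str(alt)))
    for start, ln, present in zip(indel_starts, indel_lengths, indel_present_in):
        absent_seq = seq_b if present == "A" else seq_a
        absent_seq[start: start + ln] = "-"

    def render(cls: str, noise_rng) -> str:
        s = (seq_a if cls == "A" else seq_b).copy()
        for c in noise_cols:
            if noise_rng.random() < 0.5:
                s[c] = noise_rng.choice([b for b in "ACGT" if b != s[c]])
        return "".join(s)

    sequences: dict[str, str] = {}
    class_a = [f"PAM_{k:02d}" for k in range(n_pam)]
    class_b = [f"HIM_{k:02d}" for k in range(n_him)]
    for sid in class_a:
        sequences[sid] = render("A", rng)
    for sid in class_b:
        sequences[sid] = render("B", rng)

    hybrids = [f"HYB_{k:02d}" for k in range(n_hyb_himtype + n_hyb_pamtype)]
    maternal = ["B"] * n_hyb_himtype + ["A"] * n_hyb_pamtype
    localities = {}
    him_locs = [f"loc{k:02d}" for k in range(1, 6)]
    for k, (sid, cls) in enumerate(zip(hybrids, maternal)):
        sequences[sid] = render(cls, rng)
        if cls == "A":
            localities[sid] = f"pamloc{k:02d}"  # each PAM-maternal hybrid its own site
        else:
            localities[sid] = him_locs[k % len(him_locs)]

    truth = {
        "snp_sites": snp_alleles,
        "indel_events": [
            {"start": int(s), "length": int(ln), "present_in": p}
            for s, ln, p in zip(indel_starts, indel_lengths, indel_present_in)
        ],
        "maternal": dict(zip(hybrids, maternal)),
        "localities": localities,
        "class_a_label": "PAM",
        "class_b_label": "HIM",
    }
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for sid, seq in sequences.items():
                fh.write(f">{sid}\n{seq}\n")
    return CpdnaFixture(sequences, class_a, class_b, hybrids, truth)
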