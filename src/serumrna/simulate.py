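"""Synthetic serum / bone-marrow small-RNA libraries with known ground truth.

Two layers:

* :func:`sample_fragments` draws individual 15-45 nt fragments from a
  :class:`MixtureConfig` whose defaults encode the healthy-serum landscape:
  rsRNA-dominant composition (62.86% rsRNA, 14.97% ysRNA, 4.22% tsRNA,
  3.09% miRNA), 28S/18S-dominated rsRNAs concentrated at canonical
  positional peaks, 5'-dominant tsRNAs and ysRNAs, and ~30 nt ysRNA lengths.
* :func:`simulate_cohort` simulates AML-vs-control cohorts at the feature
  level (negative-binomial counts with planted log2 fold changes and an
  exact spike-in count per library) and can expand any sample back into
  reads via the same fragment samplers, so annotation recovers the truth.

Counts are simulated at the feature level and expanded to reads afterwards;
this gives exact control over the differential-expression ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import features as feat
from .reference import (
    CYTO_TRNAS,
    MT_TRNAS,
    SPIKE_IN_ID,
    ParentRNA,
    ReferenceSet,
)

MIN_LEN, MAX_LEN = 15, 45
_LENGTHS = np.arange(MIN_LEN, MAX_LEN + 1)

SUBTYPE_5P = "five_prime"
SUBTYPE_INNER = "inner"
SUBTYPE_3P = "three_prime"
SUBTYPE_3CCA = "three_prime_cca"


@dataclass(frozen=True)
class FragmentOrigin:
    """Provenance of one simulated read on its parental RNA (1-based, incl.)."""

    parent_id: str
    start: int
    end: int
    cca_appended: bool = False

    def validate(self, parent: ParentRNA) -> None:
        limit = parent.body_length + (3 if self.cca_appended else 0)
        if not (1 <= self.start <= self.end <= limit):
            raise ValueError(f"origin {self} outside parent {parent.id}")
        if not (MIN_LEN <= self.end - self.start + 1 <= MAX_LEN):
            raise ValueError(f"origin {self} has length outside [{MIN_LEN},{MAX_LEN}]")


def discretized_normal(mean: float, sd: float) -> np.ndarray:
    """Discrete length distribution over 15-45 nt from a truncated normal."""
    p = np.exp(-0.5 * ((_LENGTHS - mean) / sd) ** 2)
    return p / p.sum()


@dataclass
class MixtureConfig:
    """Generative model of one serum small-RNA library.

    ``class_proportions`` are fractions over the biological categories;
    ``rsrna_peak_model`` holds per-parent (start, end, weight) intervals with
    ``rsrna_peak_fraction`` of that parent's reads drawn from inside them;
    ``tsrna_positional_model`` gives per-tRNA probabilities over the four
    cleavage subtypes; lengths are drawn per category from discrete
    distributions over 15-45 nt.
    """

    class_proportions: Dict[str, float]
    rsrna_parent_weights: Dict[str, float]
    rsrna_peak_model: Dict[str, List[Tuple[int, int, float]]]
    rsrna_peak_fraction: float
    tsrna_positional_model: Dict[str, Tuple[float, float, float, float]]
    tsrna_cyto_fraction: float
    ysrna_gene_weights: Dict[str, float]
    ysrna_five_prime_fraction: float
    length_distribution: Dict[str, np.ndarray]
    seed: int = 0

    def validate(self, ref: ReferenceSet) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        for frac in (self.rsrna_peak_fraction, self.tsrna_cyto_fraction,
                     self.ysrna_five_prime_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for parent_id, intervals in self.rsrna_peak_model.items():
            length = ref[parent_id].length
            for s, e, w in intervals:
                if not (1 <= s <= e <= length):
                    raise ValueError(
                        f"peak interval ({s},{e}) outside {parent_id} (len {length})"
                    )
                if w < 0:
                    raise ValueError("peak weights must be nonnegative")
        for probs in self.tsrna_positional_model.values():
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError("positional model rows must be distributions")
        for cat, dist in self.length_distribution.items():
            if abs(dist.sum() - 1.0) > 1e-9:
                raise ValueError(f"length distribution for {cat} must sum to 1")


def default_mixture_config(seed: int = 0) -> MixtureConfig:
    """Healthy-serum defaults: the reported composition and positional models."""
    class_proportions = {
        "rsRNA": 0.6286,
        "ysRNA": 0.1497,
        "tsRNA": 0.0422,
        "miRNA": 0.0309,
        "piRNA": 0.0900,
        "other_ncRNA": 0.0586,
    }
    rsrna_parent_weights = {
        "28S": 0.88, "18S": 0.10, "5S": 0.004, "5.8S": 0.004,
        "45S": 0.004, "mt-12S": 0.004, "mt-16S": 0.004,
    }
    rsrna_peak_model = {
        parent: [(s, e, 1.0) for s, e in intervals]
        for parent, intervals in feat.DEFAULT_RSRNA_PEAKS.items()
    }
    positional = {}
    for anticodon in CYTO_TRNAS:
        positional[f"tRNA-{anticodon}"] = (0.70, 0.20, 0.05, 0.05)
    for anticodon in MT_TRNAS:
        positional[f"mt-tRNA-{anticodon}"] = (0.10, 0.70, 0.12, 0.08)
    length_distribution = {
        "rsRNA": discretized_normal(33.0, 5.0),
        "ysRNA": discretized_normal(30.0, 2.0),
        "tsRNA": discretized_normal(32.0, 4.0),
        "other_ncRNA": discretized_normal(28.0, 6.0),
    }
    return MixtureConfig(
        class_proportions=class_proportions,
        rsrna_parent_weights=rsrna_parent_weights,
        rsrna_peak_model=rsrna_peak_model,
        rsrna_peak_fraction=0.9,
        tsrna_positional_model=positional,
        tsrna_cyto_fraction=0.9,
        ysrna_gene_weights={"RNY4": 0.55, "RNY1": 0.20, "RNY3": 0.15, "RNY5": 0.10},
        ysrna_five_prime_fraction=0.9,
        length_distribution=length_distribution,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Feature universe


def feature_table(mcfg: MixtureConfig, ref: ReferenceSet) -> pd.DataFrame:
    """Enumerate countable features with their baseline library proportions.

    Columns: feature_id (index), category, parent_id, kind, detail,
    proportion.  ``kind``/``detail`` drive the per-feature fragment sampler.
    """
    rows = []

    def add(fid, category, parent_id, kind, detail, prop):
        rows.append((fid, category, parent_id, kind, detail, prop))

    props = mcfg.class_proportions

    # rsRNA: peak bins on 18S/28S, parent-level elsewhere, spacer-only 45S.
    p_rs = props.get("rsRNA", 0.0)
    wsum = sum(mcfg.rsrna_parent_weights.values())
    for parent_id, w in mcfg.rsrna_parent_weights.items():
        p_parent = p_rs * w / wsum
        intervals = mcfg.rsrna_peak_model.get(parent_id)
        if intervals:
            total_w = sum(iw for _, _, iw in intervals)
            for i, (s, e, iw) in enumerate(intervals, start=1):
                add(feat.rsrna_feature(parent_id, f"#{i}"), "rsRNA", parent_id,
                    "peak", (s, e), p_parent * mcfg.rsrna_peak_fraction * iw / total_w)
            add(feat.rsrna_feature(parent_id, "-bg"), "rsRNA", parent_id,
                "uniform", None, p_parent * (1.0 - mcfg.rsrna_peak_fraction))
        elif parent_id == "45S":
            add(feat.rsrna_feature(parent_id, None), "rsRNA", parent_id,
                "spacer", None, p_parent)
        else:
            add(feat.rsrna_feature(parent_id, None), "rsRNA", parent_id,
                "uniform", None, p_parent)

    # ysRNA: gene x 5'/3'.
    p_ys = props.get("ysRNA", 0.0)
    gsum = sum(mcfg.ysrna_gene_weights.values())
    for gene, gw in mcfg.ysrna_gene_weights.items():
        p_gene = p_ys * gw / gsum
        add(feat.ysrna_feature(gene, True), "ysRNA", gene, "ysrna", "5p",
            p_gene * mcfg.ysrna_five_prime_fraction)
        add(feat.ysrna_feature(gene, False), "ysRNA", gene, "ysrna", "3p",
            p_gene * (1.0 - mcfg.ysrna_five_prime_fraction))

    # tsRNA: parent x reported cleavage group.
    p_ts = props.get("tsRNA", 0.0)
    cyto = [p for p in ref.by_category("tRNA")]
    mito = [p for p in ref.by_category("mt_tRNA")]
    for pool, pool_frac in ((cyto, mcfg.tsrna_cyto_fraction),
                            (mito, 1.0 - mcfg.tsrna_cyto_fraction)):
        for parent in pool:
            p5, pin, p3, pcca = mcfg.tsrna_positional_model[parent.id]
            p_parent = p_ts * pool_frac / len(pool)
            for group, gp in ((feat.GROUP_5P, p5), (feat.GROUP_INNER, pin),
                              (feat.GROUP_3P, p3 + pcca)):
                add(feat.tsrna_feature(parent.category, parent.subcategory, group),
                    "tsRNA", parent.id, "tsrna", group, p_parent * gp)

    # miRNA / piRNA: full-length parents, uniform weights.
    for category, kind in (("miRNA", "full"), ("piRNA", "full")):
        pool = ref.by_category(category)
        p_cat = props.get(category, 0.0)
        for parent in pool:
            add(parent.id, category, parent.id, kind, None, p_cat / len(pool))

    # Other ncRNAs: uniform substrings.
    pool = ref.by_category("other_ncRNA")
    p_other = props.get("other_ncRNA", 0.0)
    for parent in pool:
        add(parent.id, "other_ncRNA", parent.id, "uniform", None, p_other / len(pool))

    df = pd.DataFrame(
        rows, columns=["feature_id", "category", "parent_id", "kind", "detail",
                       "proportion"],
    ).set_index("feature_id")
    total = df["proportion"].sum()
    if abs(total - sum(props.values())) > 1e-9:
        raise AssertionError("feature proportions do not add up")
    df["proportion"] /= total
    return df


# ---------------------------------------------------------------------------
# Fragment samplers


def _draw_lengths(mcfg: MixtureConfig, category: str, size: int,
                  rng: np.random.Generator, max_len: int | None = None) -> np.ndarray:
    dist = mcfg.length_distribution[category]
    lengths = rng.choice(_LENGTHS, size=size, p=dist)
    if max_len is not None:
        lengths = np.minimum(lengths, max_len)
    return lengths


def _sample_feature_origins(
    row: pd.Series, n: int, mcfg: MixtureConfig, ref: ReferenceSet,
    rng: np.random.Generator,
) -> List[FragmentOrigin]:
    """Draw ``n`` fragment origins for one feature-table row."""
    parent = ref[row["parent_id"]]
    kind, detail, category = row["kind"], row["detail"], row["category"]
    L = parent.body_length
    out: List[FragmentOrigin] = []

    if kind == "full":
        return [FragmentOrigin(parent.id, 1, L)] * n

    if kind == "uniform":
        lengths = _draw_lengths(mcfg, category, n, rng, max_len=min(MAX_LEN, L))
        starts = rng.integers(1, L - lengths + 2)
        return [FragmentOrigin(parent.id, int(s), int(s + l - 1))
                for s, l in zip(starts, lengths)]

    if kind == "spacer":
        regions = [r for r in ref.spacer_regions(parent.id)
                   if r[1] - r[0] + 1 >= MIN_LEN]
        widths = np.array([e - s + 1 for s, e in regions], dtype=float)
        idx = rng.choice(len(regions), size=n, p=widths / widths.sum())
        for i in idx:
            rs, re = regions[i]
            w = re - rs + 1
            l = int(_draw_lengths(mcfg, category, 1, rng, max_len=min(MAX_LEN, w))[0])
            s = int(rng.integers(rs, re - l + 2))
            out.append(FragmentOrigin(parent.id, s, s + l - 1))
        return out

    if kind == "peak":
        a, b = detail
        w = b - a + 1
        lengths = _draw_lengths(mcfg, category, n, rng, max_len=min(MAX_LEN, w))
        starts = rng.integers(a, b - lengths + 2)
        return [FragmentOrigin(parent.id, int(s), int(s + l - 1))
                for s, l in zip(starts, lengths)]

    if kind == "ysrna":
        lengths = _draw_lengths(mcfg, category, n, rng)
        if detail == "5p":
            starts = rng.integers(1, 4, size=n)
            for s, l in zip(starts, lengths):
                e = min(int(s + l - 1), L)
                out.append(FragmentOrigin(parent.id, int(s), e))
        else:
            ends = rng.integers(L - 2, L + 1, size=n)
            for e, l in zip(ends, lengths):
                l = min(int(l), int(e) - 4 + 1)
                out.append(FragmentOrigin(parent.id, int(e - l + 1), int(e)))
        return out

    if kind == "tsrna":
        p5, pin, p3, pcca = mcfg.tsrna_positional_model[parent.id]
        if detail == feat.GROUP_5P:
            subtypes = [SUBTYPE_5P] * n
        elif detail == feat.GROUP_INNER:
            subtypes = [SUBTYPE_INNER] * n
        else:
            pr = p3 / (p3 + pcca) if (p3 + pcca) > 0 else 1.0
            subtypes = np.where(rng.random(n) < pr, SUBTYPE_3P, SUBTYPE_3CCA)
        lengths = _draw_lengths(mcfg, category, n, rng)
        for sub, l in zip(subtypes, lengths):
            l = int(l)
            if sub == SUBTYPE_5P:
                s = int(rng.integers(1, 4))
                e = min(s + l - 1, L)
            elif sub == SUBTYPE_INNER:
                l = min(l, L - 6)
                s = int(rng.integers(4, L - 3 - l + 2))
                e = s + l - 1
            elif sub == SUBTYPE_3P:
                e = int(rng.integers(L - 2, L + 1))
                l = min(l, e - 4 + 1)
                s = e - l + 1
            else:  # three_prime_cca: runs into the appended tail
                e = int(rng.integers(L + 1, L + 4))
                l = min(l, e - 4 + 1)
                s = e - l + 1
            out.append(FragmentOrigin(parent.id, s, e, cca_appended=sub == SUBTYPE_3CCA))
        return out

    raise ValueError(f"unknown sampler kind {kind!r}")


def _subtype_of(origin: FragmentOrigin, ref: ReferenceSet) -> str:
    parent = ref[origin.parent_id]
    if parent.category not in ("tRNA", "mt_tRNA"):
        return ""
    from .fragments import classify_tsrna_subtype

    return classify_tsrna_subtype(origin.start, origin.end, parent.body_length)


def fragment_sequence(origin: FragmentOrigin, ref: ReferenceSet) -> str:
    seq = ref[origin.parent_id].sequence
    if origin.cca_appended:
        seq = seq + "CCA"
    return seq[origin.start - 1 : origin.end]


def sample_fragments(
    mcfg: MixtureConfig, ref: ReferenceSet, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw ``n`` reads from the mixture; returns the ground-truth table.

    Columns: read_id, sequence, category, feature_id, parent_id, start, end,
    cca_appended, subtype (tsRNA cleavage subtype, empty otherwise).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mcfg.validate(ref)
    rng = np.random.default_rng(mcfg.seed if seed is None else seed)
    table = feature_table(mcfg, ref)
    counts = rng.multinomial(n, table["proportion"].to_numpy())

    records = []
    for (fid, row), c in zip(table.iterrows(), counts):
        if c == 0:
            continue
        for origin in _sample_feature_origins(row, int(c), mcfg, ref, rng):
            records.append(
                (fragment_sequence(origin, ref), row["category"], fid,
                 origin.parent_id, origin.start, origin.end, origin.cca_appended,
                 _subtype_of(origin, ref))
            )
    df = pd.DataFrame(
        records, columns=["sequence", "category", "feature_id", "parent_id",
                          "start", "end", "cca_appended", "subtype"],
    )
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "read_id", [f"r{i:06d}" for i in range(1, len(df) + 1)])
    return df


# ---------------------------------------------------------------------------
# Cohorts


#: Planted AML marker panel: six 5'-tsRNA features with strong fold changes,
#: echoing the anticodons recurrently reported for serum tsRNA signatures.
DEFAULT_TSRNA_PANEL = (
    "tsRNA-Ala-TGC-5p",
    "tsRNA-Gly-CCC-5p",
    "tsRNA-Gly-GCC-5p",
    "tsRNA-Leu-CAG-5p",
    "tsRNA-Leu-CAA-5p",
    "tsRNA-Lys-TTT-5p",
)


def default_aml_effects() -> Dict[str, float]:
    """Planted log2 fold changes: a clean 6-tsRNA panel plus a broader,
    weaker set of dysregulated miRNAs (more markers, each less decisive)."""
    effects = {fid: 2.0 for fid in DEFAULT_TSRNA_PANEL}
    mirna_up = ["mir-451a", "mir-146a"] + [f"mir-s{i:03d}" for i in (1, 4, 7, 10, 13, 16, 19, 22)]
    mirna_dn = ["mir-320a"] + [f"mir-s{i:03d}" for i in (2, 5, 8)]
    for m in mirna_up:
        effects[m] = 1.3
    for m in mirna_dn:
        effects[m] = -1.2
    return effects


@dataclass
class CohortConfig:
    """Design of a simulated case/control (optionally paired) cohort."""

    n_control: int = 12
    n_aml: int = 30
    paired_bms: bool = False
    de_effects: Dict[str, float] = field(default_factory=dict)
    nb_dispersion: float = 0.05
    library_size_range: Tuple[int, int] = (40_000, 60_000)
    spike_in_count: int = 1_000
    bms_shared_signal_fraction: float = 0.8
    subject_sigma: float = 1.2
    seed: int = 0

    def validate(self, table: pd.DataFrame) -> None:
        if self.n_control < 2 or self.n_aml < 2:
            raise ValueError("need at least 2 samples per group")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.spike_in_count <= 0:
            raise ValueError("spike_in_count must be positive")
        if not 0.0 <= self.bms_shared_signal_fraction <= 1.0:
            raise ValueError("bms_shared_signal_fraction must be in [0, 1]")
        unknown = set(self.de_effects) - set(table.index)
        if unknown:
            raise ValueError(f"de_effects name unknown features: {sorted(unknown)}")


@dataclass
class SimulatedCohort:
    """Feature x sample counts with design metadata and generator truth."""

    counts: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    mixture: MixtureConfig
    reference: ReferenceSet
    config: CohortConfig

    def expand_reads(self, sample_id: str, seed: int) -> pd.DataFrame:
        """Regenerate a read-level truth table for one sample's counts."""
        rng = np.random.default_rng(seed)
        records = []
        for fid, c in self.counts[sample_id].items():
            c = int(c)
            if c == 0:
                continue
            if fid == SPIKE_IN_ID:
                parent = self.reference[SPIKE_IN_ID]
                seq = parent.sequence
                records.extend(
                    (seq, "spike_in", fid, fid, 1, parent.length, False, "")
                    for _ in range(c)
                )
                continue
            row = self.features.loc[fid]
            for origin in _sample_feature_origins(row, c, self.mixture,
                                                  self.reference, rng):
                records.append(
                    (fragment_sequence(origin, self.reference), row["category"],
                     fid, origin.parent_id, origin.start, origin.end,
                     origin.cca_appended, _subtype_of(origin, self.reference))
                )
        df = pd.DataFrame(
            records, columns=["sequence", "category", "feature_id", "parent_id",
                              "start", "end", "cca_appended", "subtype"],
        )
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        df.insert(0, "read_id",
                  [f"{sample_id}.r{i:06d}" for i in range(1, len(df) + 1)])
        return df


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    size = 1.0 / phi
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_cohort(
    ccfg: CohortConfig, mcfg: MixtureConfig, ref: ReferenceSet
) -> SimulatedCohort:
    """Simulate a cohort of libraries at the feature level.

    Per sample, feature counts are negative binomial with mean
    ``library_size x baseline proportion`` (shifted by ``de_effects`` in AML
    samples) and dispersion phi.  With ``paired_bms`` each subject carries a
    latent per-feature log-normal expression vector; the BMS replicate mixes
    that vector with independent noise according to
    ``bms_shared_signal_fraction``, so the paired compartments share exactly
    the configured amount of subject-level signal.  Every library receives
    exactly ``spike_in_count`` spike-in reads.
    """
    table = feature_table(mcfg, ref)
    ccfg.validate(table)
    rng = np.random.default_rng(ccfg.seed)

    base = table["proportion"].to_numpy()
    lfc = np.array([ccfg.de_effects.get(f, 0.0) for f in table.index])
    nfeat = len(table)
    lo, hi = ccfg.library_size_range

    subjects = [(f"HC{i:02d}", "control") for i in range(1, ccfg.n_control + 1)]
    subjects += [(f"AML{i:02d}", "AML") for i in range(1, ccfg.n_aml + 1)]

    sample_rows, columns = [], {}
    w = ccfg.bms_shared_signal_fraction
    for subject, group in subjects:
        effect = np.where(group == "AML", 1.0, 0.0) * lfc
        scale = base * np.exp2(effect)
        if ccfg.paired_bms:
            a = rng.normal(0.0, ccfg.subject_sigma, size=nfeat)
            b = rng.normal(0.0, ccfg.subject_sigma, size=nfeat)
            latents = {"PBS": a, "BMS": w * a + np.sqrt(1.0 - w * w) * b}
        else:
            latents = {"PBS": np.zeros(nfeat)}
        for compartment, latent in latents.items():
            lib = int(rng.integers(lo, hi + 1))
            mu = lib * scale * np.exp(latent - 0.5 * ccfg.subject_sigma ** 2
                                      * float(ccfg.paired_bms))
            counts = _nb_draw(rng, mu, ccfg.nb_dispersion)
            sid = f"{subject}-{compartment}" if ccfg.paired_bms else subject
            columns[sid] = counts
            sample_rows.append((sid, group, compartment, subject, lib))

    counts = pd.DataFrame(columns, index=table.index)
    counts.loc[SPIKE_IN_ID] = ccfg.spike_in_count
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "group", "compartment", "subject", "library_size"],
    ).set_index("sample_id")

    features = table.copy()
    features["true_log2fc"] = lfc
    spike_row = pd.DataFrame(
        [["spike_in", SPIKE_IN_ID, "full", None, 0.0, 0.0]],
        columns=["category", "parent_id", "kind", "detail", "proportion",
                 "true_log2fc"],
        index=pd.Index([SPIKE_IN_ID], name="feature_id"),
    )
    features = pd.concat([features, spike_row])
    counts = counts.loc[features.index]

    return SimulatedCohort(counts=counts, samples=samples, features=features,
                           mixture=mcfg, reference=ref, config=ccfg)
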