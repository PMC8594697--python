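"""Seeded simulator of two-condition replicated bisulfite methylomes.

The generator emulates a plant WGBS comparison between a reference condition
(e.g. the adult donor tree) and a test condition (seedling or young graft):

* cytosine positions are drawn per context with CHH-dominant densities
  (counting both strands, roughly a third of bases are cytosines and about
  three quarters of those are CHH, as in apple/Arabidopsis-like genomes);
* every cytosine has a context baseline methylation level (CG 60%, CHG 40%,
  CHH 10%); inside an *injected* region of matching context the test
  condition's level is shifted by a signed delta and clipped to [0, 100];
* per replicate, read coverage is Poisson (mean 14, truncated at >= 1 so the
  site appears in the call file) and the methylated count is binomial at the
  site's level.

There is no extra between-replicate biological variance: replicates differ
only by sampling noise, which is the regime the window t-test assumes under
its null.  Expression ratios are coupled to promoter CHH methylation with a
configurable effect size, and p-values arise from a per-gene two-sample
t-test on simulated replicate expression values, so the resulting table is a
faithful stand-in for a normalized differential-transcription contract.

Everything derives from ``SimSpec.seed`` through independent child streams
ordered by genomic coordinate, so identical specs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .dmr_caller import MethylomeSet
from .io import CONTEXTS

__all__ = ["SimSpec", "Injection", "simulate_methylomes", "simulate_features",
           "make_injections", "make_promoter_injections", "simulate_expression",
           "make_bin_map", "evaluate_calls", "EvaluationResult"]


class Injection(NamedTuple):
    """A ground-truth differentially methylated region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    context: str
    delta: float  # pp added to the test condition's level, then clipped


def _default_densities():
    return {"CG": 0.04, "CHG": 0.04, "CHH": 0.30}


def _default_baselines():
    return {"CG": 60.0, "CHG": 40.0, "CHH": 10.0}


@dataclass
class SimSpec:
    seed: int
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    densities: dict = field(default_factory=_default_densities)   # per-bp, both strands
    baselines: dict = field(default_factory=_default_baselines)   # %
    coverage_mean: float = 14.0
    n_replicates: int = 3
    injections: list = field(default_factory=list)
    n_genes: int = 150
    n_tes: int = 150
    condition_ref: str = "OG"
    condition_test: str = "SD"
    expression_effect: float = 30.0  # log2 units per unit promoter-CHH delta fraction
    expression_noise_sd: float = 0.35  # sd of the realized log2 ratio around its mean
    n_expr_replicates: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimSpec.seed is mandatory")
        for ctx, d in self.densities.items():
            if not (0 < d <= 1):
                raise ValueError(f"density for {ctx} must be in (0, 1]")
        if sum(self.densities.values()) > 1:
            raise ValueError("context densities must sum to <= 1")
        self._validate_injections()

    def _validate_injections(self):
        by_chrom = {}
        for inj in self.injections:
            inj = Injection(*inj)
            if not (0 <= inj.start < inj.end <= self.chrom_length):
                raise ValueError(f"injection {inj} outside chromosome bounds")
            by_chrom.setdefault(inj.chrom, []).append(inj)
        for chrom, injs in by_chrom.items():
            injs.sort(key=lambda i: i.start)
            for a, b in zip(injs, injs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping injections on {chrom}: {a} / {b}")

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_lengths(self):
        return {c: self.chrom_length for c in self.chrom_names()}

    def rng(self, stream):
        """Independent deterministic child stream (0=sites, 1=features, ...)."""
        return np.random.default_rng([int(stream), int(self.seed)])


def _truncated_poisson(rng, mean, size):
    """Poisson(mean) conditioned on >= 1 (zero-coverage sites do not exist)."""
    cov = rng.poisson(mean, size)
    zeros = cov == 0
    while zeros.any():
        cov[zeros] = rng.poisson(mean, int(zeros.sum()))
        zeros = cov == 0
    return cov


def simulate_methylomes(spec):
    """Draw both conditions' replicated call tables and the truth table.

    Returns ``(ref_set, test_set, truth)`` where truth lists the injected
    regions with context, delta and expected call direction.
    """
    spec._validate_injections()
    rng = spec.rng(0)
    dens = [spec.densities.get(c, 0.0) for c in CONTEXTS]
    edges = np.cumsum(dens)

    sites = []
    for chrom in spec.chrom_names():
        u = rng.random(spec.chrom_length)
        strand_draw = rng.random(spec.chrom_length) < 0.5
        ctx_idx = np.searchsorted(edges, u, side="right")  # 3 => not a cytosine
        keep = ctx_idx < len(CONTEXTS)
        pos = np.nonzero(keep)[0] + 1  # 1-based
        ctx = np.asarray(CONTEXTS)[ctx_idx[keep]]
        level = np.array([spec.baselines[c] for c in CONTEXTS])[ctx_idx[keep]]
        level_test = level.copy()
        for inj in (Injection(*i) for i in spec.injections):
            if inj.chrom != chrom:
                continue
            mask = (pos - 1 >= inj.start) & (pos - 1 < inj.end) & (ctx == inj.context)
            level_test[mask] = np.clip(level_test[mask] + inj.delta, 0.0, 100.0)
        sites.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "strand": np.where(strand_draw[pos - 1], "+", "-"),
            "context": ctx, "level_ref": level, "level_test": level_test,
        }))
    sites = pd.concat(sites, ignore_index=True)

    def draw_condition(level_col, condition, rep_offset):
        samples = {}
        for r in range(spec.n_replicates):
            cov = _truncated_poisson(rng, spec.coverage_mean, len(sites))
            meth = rng.binomial(cov, sites[level_col].to_numpy() / 100.0)
            df = pd.DataFrame({
                "chrom": sites["chrom"], "pos": sites["pos"],
                "strand": sites["strand"], "context": sites["context"],
                "n_meth": meth.astype(np.int64), "n_total": cov.astype(np.int64),
            })
            sample_id = f"{condition}_rep{r + 1}"
            df.attrs["sample_id"] = sample_id
            df.attrs["condition"] = condition
            samples[sample_id] = df
        return MethylomeSet(condition=condition, samples=samples)

    ref_set = draw_condition("level_ref", spec.condition_ref, 0)
    test_set = draw_condition("level_test", spec.condition_test, spec.n_replicates)

    truth = pd.DataFrame(
        [Injection(*i) for i in spec.injections],
        columns=["chrom", "start", "end", "context", "delta"],
    )
    truth["direction"] = np.where(truth["delta"] < 0, "hypo", "hyper") \
        if len(truth) else pd.Series(dtype=str)
    return ref_set, test_set, truth


def simulate_features(spec):
    """Deterministic gene/TE annotation: features in jittered, disjoint slots."""
    rng = spec.rng(1)
    rows = []
    per_chrom_genes = spec.n_genes // spec.n_chroms
    per_chrom_tes = spec.n_tes // spec.n_chroms
    for ci, chrom in enumerate(spec.chrom_names()):
        n_slots = per_chrom_genes + per_chrom_tes
        if n_slots == 0:
            continue
        slot = spec.chrom_length // n_slots
        if slot < 4700:
            raise ValueError(
                f"feature slots of {slot} bp are too small for 2-kb flanks; "
                "reduce n_genes/n_tes or lengthen chromosomes")
        kinds = np.array(["gene"] * per_chrom_genes + ["TE"] * per_chrom_tes)
        rng.shuffle(kinds)
        for si, kind in enumerate(kinds):
            base = si * slot
            if kind == "gene":
                length = int(rng.integers(1000, min(4000, slot - 3600)))
            else:
                length = int(rng.integers(400, min(2500, slot - 3600)))
            # keep a >= 2.1-kb upstream margin so flank regions stay in the slot
            lo = base + 2100
            hi = base + slot - 2100 - length
            start = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            num = ci * n_slots + si
            fid = (f"g{num:04d}" if kind == "gene" else f"te{num:04d}")
            label = "" if kind == "gene" else ("ClassI" if rng.random() < 0.6 else "ClassII")
            rows.append((fid, chrom, start, start + length, strand, kind, label))
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end",
                                       "strand", "kind", "class_label"])


def make_injections(spec, n, length=500, context="CHH", delta=-30.0, gap=500):
    """n non-overlapping injected regions spread evenly over the genome."""
    pitch = length + gap
    per_chrom = spec.chrom_length // pitch
    total = per_chrom * spec.n_chroms
    if n > total:
        raise ValueError(f"cannot place {n} injections of pitch {pitch}")
    rng = spec.rng(2)
    slots = rng.choice(total, size=n, replace=False)
    slots.sort()
    out = []
    for s in slots:
        chrom = spec.chrom_names()[int(s) // per_chrom]
        start = (int(s) % per_chrom) * pitch
        out.append(Injection(chrom, start, start + length, context, float(delta)))
    return out


def make_promoter_injections(spec, features, n, length=500, context="CHH",
                             delta=-30.0):
    """Injections centred in the 2-kb promoters of n distinct genes.

    ``delta`` may be a scalar or a ``(low, high)`` pair, in which case each
    injection draws its shift uniformly from that range (a dose spread, so
    the methylation-expression regression has genuine leverage).  Returns
    ``(injections, coupled_gene_ids)``; these genes are the truly
    methylation-coupled set for expression simulation.
    """
    genes = features[features["kind"] == "gene"].reset_index(drop=True)
    if n > len(genes):
        raise ValueError(f"cannot couple {n} genes, only {len(genes)} available")
    rng = spec.rng(3)
    chosen = rng.choice(len(genes), size=n, replace=False)
    chosen.sort()
    if np.iterable(delta):
        lo, hi = delta
        deltas = rng.uniform(lo, hi, size=n)
    else:
        deltas = np.full(n, float(delta))
    injections, coupled = [], []
    for i, d in zip(chosen, deltas):
        g = genes.iloc[int(i)]
        if g.strand == "+":
            start = int(g.start) - (2000 + length) // 2 - length // 2
        else:
            start = int(g.end) + (2000 - length) // 2
        start = max(0, min(start, spec.chrom_length - length))
        injections.append(Injection(g.chrom, start, start + length, context,
                                    float(d)))
        coupled.append(g.feature_id)
    return injections, coupled


def promoter_delta(spec, features, truth, flank=2000):
    """Summed injected CHH delta overlapping each gene's strand-aware promoter."""
    out = {}
    for g in features[features["kind"] == "gene"].itertuples():
        if g.strand == "+":
            ps, pe = g.start - flank, g.start
        else:
            ps, pe = g.end, g.end + flank
        d = 0.0
        for inj in truth.itertuples():
            if inj.context == "CHH" and inj.chrom == g.chrom \
                    and inj.start < pe and ps < inj.end:
                d += inj.delta
        out[g.feature_id] = d
    return out


def simulate_expression(spec, features, truth):
    """Differential-transcription table coupled to promoter CHH methylation.

    The expected log2 ratio of a gene is ``-effect * (promoter CHH delta /
    100)``; the realized ratio is the difference of replicate means where the
    replicate noise is scaled so the ratio's own noise sd equals
    ``expression_noise_sd``.  p-values come from a pooled two-sample t-test on
    the replicate values.  TEs (and uncoupled genes) have expected ratio 0.
    """
    rng = spec.rng(4)
    deltas = promoter_delta(spec, features, truth)
    n_rep = spec.n_expr_replicates
    rep_sd = spec.expression_noise_sd * np.sqrt(n_rep / 2.0)
    rows = []
    for f in features.itertuples():
        true_ratio = 0.0
        if f.kind == "gene":
            true_ratio = -spec.expression_effect * deltas.get(f.feature_id, 0.0) / 100.0
        a = rng.normal(0.0, rep_sd, n_rep) if rep_sd > 0 else np.zeros(n_rep)
        b = true_ratio + (rng.normal(0.0, rep_sd, n_rep) if rep_sd > 0
                          else np.zeros(n_rep))
        ratio = float(b.mean() - a.mean())
        if rep_sd > 0:
            p = float(stats.ttest_ind(b, a, equal_var=True).pvalue)
        else:
            p = 0.0 if ratio != 0 else 1.0
        rows.append((f.feature_id, f.kind, ratio, p))
    return pd.DataFrame(rows, columns=["transcript_id", "kind", "ratio", "p_value"])


def make_bin_map(spec, features):
    """Mercator-style BIN map over the simulated genes.

    A handful of top-level classes with plant-flavoured names; coupled-gene
    enrichment is not engineered here — assignment is random and seeded.
    """
    classes = [
        ("1", "Photosynthesis"),
        ("15", "RNA biosynthesis"),
        ("17", "Protein biosynthesis"),
        ("19", "Protein degradation"),
        ("24", "Solute transport"),
        ("50", "Enzyme families"),
    ]
    rng = spec.rng(5)
    rows = []
    genes = features[features["kind"] == "gene"]
    draws = rng.integers(0, len(classes), size=len(genes))
    for (_, g), d in zip(genes.iterrows(), draws):
        code, name = classes[int(d)]
        rows.append((code, name, g.feature_id.lower()))
    return pd.DataFrame(rows, columns=["bincode", "name", "identifier"])


@dataclass
class EvaluationResult:
    """Recovery of injected regions by called DMRs."""

    sensitivity: float
    precision: float            # NaN when there are no calls
    fdp: float                  # 1 - precision (NaN likewise)
    n_injections: int
    n_calls: int
    per_context: dict = field(default_factory=dict)


def _match(calls, truth):
    """Boolean masks: calls matching truth and truth matched by calls.

    A call matches an injection when their intervals overlap on the same
    chromosome with the same context and direction.
    """
    call_hit = np.zeros(len(calls), bool)
    truth_hit = np.zeros(len(truth), bool)
    t_by = {}
    for ti, t in enumerate(truth.itertuples()):
        t_by.setdefault((t.chrom, t.context, t.direction), []).append(
            (t.start, t.end, ti))
    for ci, c in enumerate(calls.itertuples()):
        for (ts, te, ti) in t_by.get((c.chrom, c.context, c.direction), ()):
            if c.start < te and ts < c.end:
                call_hit[ci] = True
                truth_hit[ti] = True
    return call_hit, truth_hit


def evaluate_calls(called_dmrs, truth):
    """Sensitivity and precision of a DMR call set against the truth table.

    Sensitivity = matched injections / injections; precision = matched calls
    / calls (undefined when there are no calls).  ``per_context`` holds the
    same pair restricted to each injected context.
    """
    call_hit, truth_hit = _match(called_dmrs, truth)
    n_inj, n_calls = len(truth), len(called_dmrs)
    sens = float(truth_hit.sum() / n_inj) if n_inj else float("nan")
    prec = float(call_hit.sum() / n_calls) if n_calls else float("nan")
    per_context = {}
    for ctx in sorted(truth["context"].unique()) if n_inj else []:
        tmask = (truth["context"] == ctx).to_numpy()
        cmask = (called_dmrs["context"] == ctx).to_numpy() if n_calls else \
            np.zeros(0, bool)
        s = float(truth_hit[tmask].sum() / tmask.sum())
        p = float(call_hit[cmask].sum() / cmask.sum()) if cmask.sum() else float("nan")
        per_context[ctx] = {"sensitivity": s, "precision": p,
                            "n_injections": int(tmask.sum()),
                            "n_calls": int(cmask.sum())}
    return EvaluationResult(
        sensitivity=sens, precision=prec,
        fdp=(1.0 - prec) if n_calls else float("nan"),
        n_injections=n_inj, n_calls=n_calls, per_context=per_context)
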