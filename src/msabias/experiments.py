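"""End-to-end simulation experiments.

Four study designs, each a pure function of (config, master seed):

* ``divergence`` — balanced-tree simulations across a tree-length grid;
  quantifies tree-length bias, per-branch-class error and the relation
  between alignment error and branch-length error.
* ``otu_scaling`` — the balanced tree embedded in 64/512-leaf supertrees;
  the eight-taxon sub-alignment is extracted after aligning everything and
  its inferred tree length compared across OTU counts.
* ``polytomy`` — the degree-4 multifurcation design; how often maximum
  likelihood resolves it to the long-branch-attraction (LBA) pairing, and
  SH-test rejection rates of LBA vs non-LBA resolutions.
* ``felsenstein`` — α×β grids of Felsenstein-style trees; frequency of
  recovering the generating topology under true-alignment ML, true-alignment
  parsimony, and ML on the builtin aligner's output.

Per-replicate seeds derive from the master seed by a counter-based scheme
(SeedSequence spawn keys), so all analysis arms see identical simulated
data and comparisons between arms are paired.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import align as al
from . import inference as inf
from . import shtest as sh
# direct names: the package re-exports a function named `simulate`, which
# shadows the submodule as a package attribute
from .simulate import NO_INDELS, default_indel_params
from .simulate import simulate as _simulate
from . import trees as tr
from .substitution import (
    STUDY_GAMMA_SHAPE,
    build_empirical_aa,
    discretize_gamma,
    study_gtr_model,
)

logger = logging.getLogger("msabias")

#: ratio of nucleotide to amino-acid root lengths (three codon positions)
NT_LENGTH_FACTOR = 3

DEFAULT_TREE_LENGTHS = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
DEFAULT_ROOT_LENGTHS_AA = (102, 204, 408, 816)


@dataclass
class ExperimentConfig:
    """Configuration shared by the four experiment drivers.

    ``root_length`` is always in amino-acid units; nucleotide runs use three
    times as many sites.  Reduce ``replicates`` and the grids for desk-scale
    runs; statistical tolerances must widen accordingly.
    """

    experiment: str = "divergence"
    data_type: str = "nt"                       # "nt" | "aa"
    replicates: int = 200
    seed: int = 0
    aligners: tuple = ("true", "builtin")
    tree_lengths: tuple = DEFAULT_TREE_LENGTHS
    root_length: int = 408                      # aa units
    root_lengths: tuple = DEFAULT_ROOT_LENGTHS_AA
    otu_counts: tuple = (8, 64, 512)
    alpha_values: tuple = tuple(np.round(np.arange(1, 11) * 0.025, 4))
    beta_values: tuple = tuple(np.round(0.25 + np.arange(10) * 0.125, 4))
    felsenstein_taxa: int = 8
    felsenstein_internal: float | None = None   # default: co-varies with alpha
    estimate_shape: bool = True
    n_bootstrap: int = 1000
    sh_alpha: float = 0.05
    indels: bool = True

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.data_type not in ("nt", "aa"):
            raise ValueError("data_type must be 'nt' or 'aa'")


def _setup(config):
    if config.data_type == "nt":
        model = study_gtr_model()
    else:
        model = build_empirical_aa("WAG")
    gamma = discretize_gamma(STUDY_GAMMA_SHAPE, 4)
    indels = (
        default_indel_params(model.n_states) if config.indels else NO_INDELS
    )
    return model, gamma, indels


def _sites(config, root_length_aa=None):
    n = root_length_aa if root_length_aa is not None else config.root_length
    return n * NT_LENGTH_FACTOR if config.data_type == "nt" else n


def derive_seed(master: int, *key) -> int:
    """Deterministic child seed (< 2^31) from a master seed and counters."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def _aligned(ts, arm, model):
    if arm == "true":
        return ts.alignment
    if arm == "builtin":
        msa, _ = al.progressive_align(ts.sequences, al.AlignerConfig(model))
        return msa
    raise ValueError(f"unknown aligner arm {arm!r}")


def _branch_class_rows(fit):
    rows = []
    for node in fit.tree.postorder():
        if node is fit.tree.root or node.branch_class is None:
            continue
        rows.append((node.branch_class, node.length))
    return rows


def _quartiles(values):
    lq, med, uq = np.percentile(values, [25, 50, 75])
    return {"lower_quartile": lq, "median": med, "upper_quartile": uq}


# ---------------------------------------------------------------------------


def run_divergence(config: ExperimentConfig):
    """Tree-length bias and branch-class error on the balanced tree.

    Returns ``{"replicates": tidy per-replicate table, "summary":
    per-condition medians, "branch_classes": per-class quartiles}``.
    """
    from . import compare as cmp

    model, gamma, indels = _setup(config)
    nsites = _sites(config)
    records, class_records, failures = [], [], 0
    for ci, tree_length in enumerate(config.tree_lengths):
        tree = tr.make_balanced_tree(tree_length)
        per_branch_truth = tree_length / 13.0
        for rep in range(config.replicates):
            rep_seed = derive_seed(config.seed, 1, ci, rep)
            try:
                ts = _simulate(tree, model, gamma, indels, nsites, rep_seed)
                for arm in config.aligners:
                    msa = _aligned(ts, arm, model)
                    fit = inf.optimize_branch_lengths(
                        msa, tree, model, gamma,
                        estimate_shape=config.estimate_shape,
                    )
                    est_tl = sum(fit.branch_lengths.values())
                    dist = cmp.msa_distance(msa, ts.alignment)
                    # per-branch absolute errors on the unrooted 13 branches
                    errors = [
                        abs(n.length - per_branch_truth)
                        for n in fit.tree.postorder()
                        if n is not fit.tree.root
                    ]
                    records.append(
                        dict(
                            tree_length=tree_length,
                            replicate=rep,
                            aligner=arm,
                            inferred_tree_length=est_tl,
                            msa_distance=dist,
                            cumulative_branch_error=float(np.sum(errors)),
                            alignment_length=msa.n_columns,
                            converged=fit.converged,
                        )
                    )
                    for cls, length in _branch_class_rows(fit):
                        class_records.append(
                            dict(
                                tree_length=tree_length,
                                replicate=rep,
                                aligner=arm,
                                branch_class=cls,
                                estimate=length,
                                expected=per_branch_truth,
                            )
                        )
            except Exception:  # noqa: BLE001 - replicate-level accounting
                logger.exception(
                    "divergence replicate failed (TL=%s rep=%d)", tree_length, rep
                )
                failures += 1
    reps = pd.DataFrame(records)
    summary = (
        reps.groupby(["tree_length", "aligner"])
        .agg(
            median_inferred_tree_length=("inferred_tree_length", "median"),
            mean_msa_distance=("msa_distance", "mean"),
            mean_cumulative_branch_error=("cumulative_branch_error", "mean"),
            n=("replicate", "count"),
        )
        .reset_index()
    )
    classes = pd.DataFrame(class_records)
    class_summary = (
        classes.groupby(["tree_length", "aligner", "branch_class"])["estimate"]
        .apply(lambda v: pd.Series(_quartiles(v)))
        .unstack()
        .reset_index()
        if len(classes)
        else pd.DataFrame()
    )
    if len(class_summary):
        class_summary["expected"] = class_summary["tree_length"] / 13.0
    return {
        "replicates": reps,
        "summary": summary,
        "branch_classes": class_summary,
        "failures": failures,
    }


def run_otu_scaling(config: ExperimentConfig):
    """Inferred eight-taxon tree length after aligning 8/64/512 OTUs."""
    model, gamma, indels = _setup(config)
    nsites = _sites(config)
    core = tr.make_balanced_tree(6.0)
    records, failures = [], 0
    for ci, n_otus in enumerate(config.otu_counts):
        if n_otus == 8:
            big, core_names = core, sorted(core.leaf_names())
        else:
            big, core_names = tr.embed_in_supertree(
                core, n_otus, derive_seed(config.seed, 2, ci)
            )
        for rep in range(config.replicates):
            rep_seed = derive_seed(config.seed, 2, ci, rep)
            try:
                ts = _simulate(big, model, gamma, indels, nsites, rep_seed)
                for arm in config.aligners:
                    full = _aligned(ts, arm, model)
                    sub = al.extract_subalignment(full, core_names)
                    fit = inf.optimize_branch_lengths(
                        sub, core, model, gamma,
                        estimate_shape=config.estimate_shape,
                    )
                    records.append(
                        dict(
                            n_otus=n_otus,
                            replicate=rep,
                            aligner=arm,
                            inferred_tree_length=sum(fit.branch_lengths.values()),
                            alignment_length=full.n_columns,
                            sub_alignment_length=sub.n_columns,
                            converged=fit.converged,
                        )
                    )
            except Exception:
                logger.exception(
                    "otu_scaling replicate failed (n=%d rep=%d)", n_otus, rep
                )
                failures += 1
    reps = pd.DataFrame(records)
    summary = (
        reps.groupby(["n_otus", "aligner"])
        .agg(
            median_inferred_tree_length=("inferred_tree_length", "median"),
            n=("replicate", "count"),
        )
        .reset_index()
    )
    return {"replicates": reps, "summary": summary, "failures": failures}


def run_polytomy(config: ExperimentConfig):
    """LBA-resolution frequency and SH rejection rates for the polytomy tree."""
    model, gamma, indels = _setup(config)
    base = tr.make_polytomy_tree()
    candidates, lba_index = tr.resolve_polytomy(base)
    labels = ["LBA" if i == lba_index else "non-LBA" for i in range(3)]
    records, sh_records, failures = [], [], 0
    for ci, root_aa in enumerate(config.root_lengths):
        nsites = _sites(config, root_aa)
        for rep in range(config.replicates):
            rep_seed = derive_seed(config.seed, 3, ci, rep)
            try:
                ts = _simulate(base, model, gamma, indels, nsites, rep_seed)
                for arm in config.aligners:
                    msa = _aligned(ts, arm, model)
                    choice, fits = inf.select_topology(
                        msa, candidates, model, gamma,
                        estimate_shape=config.estimate_shape,
                    )
                    L = np.vstack([f.per_site_log_likelihoods for f in fits])
                    res = sh.sh_test(
                        L,
                        n_bootstrap=config.n_bootstrap,
                        seed=derive_seed(config.seed, 3, ci, rep, 7),
                        alpha=config.sh_alpha,
                    )
                    records.append(
                        dict(
                            root_length=root_aa,
                            replicate=rep,
                            aligner=arm,
                            lba_weight=float(choice.weights[lba_index]),
                            weights=tuple(np.round(choice.weights, 6)),
                            best=int(np.argmax(choice.weights)),
                        )
                    )
                    for lab, p, rej in zip(labels, res.p_values, res.rejected):
                        sh_records.append(
                            dict(
                                root_length=root_aa,
                                replicate=rep,
                                aligner=arm,
                                candidate_class=lab,
                                p_value=float(p),
                                rejected=bool(rej),
                            )
                        )
            except Exception:
                logger.exception(
                    "polytomy replicate failed (root=%d rep=%d)", root_aa, rep
                )
                failures += 1
    reps = pd.DataFrame(records)
    summary = (
        reps.groupby(["root_length", "aligner"])
        .agg(lba_frequency=("lba_weight", "mean"), n=("replicate", "count"))
        .reset_index()
    )
    shd = pd.DataFrame(sh_records)
    sh_summary = (
        shd.groupby(["root_length", "aligner", "candidate_class"])
        .agg(rejection_rate=("rejected", "mean"), n=("rejected", "count"))
        .reset_index()
    )
    return {
        "replicates": reps,
        "summary": summary,
        "sh_replicates": shd,
        "sh_summary": sh_summary,
        "failures": failures,
    }


def run_felsenstein(config: ExperimentConfig):
    """Correct-tree frequency grids for the Felsenstein-zone design."""
    model, gamma, indels = _setup(config)
    nsites = _sites(config)
    arms = []
    for a in config.aligners:
        if a == "true":
            arms.extend(["true-ml", "true-mp"])
        else:
            arms.append(f"{a}-ml")
    records, failures = [], 0
    for ai, alpha in enumerate(config.alpha_values):
        for bi, beta in enumerate(config.beta_values):
            internal = (
                config.felsenstein_internal
                if config.felsenstein_internal is not None
                else alpha
            )
            cands, correct, lba = tr.felsenstein_candidates(
                alpha, beta, internal, config.felsenstein_taxa
            )
            gen = cands[correct]
            for rep in range(config.replicates):
                rep_seed = derive_seed(config.seed, 4, ai, bi, rep)
                try:
                    ts = _simulate(gen, model, gamma, indels, nsites, rep_seed)
                    for arm in arms:
                        src = "true" if arm.startswith("true") else arm[: -3]
                        msa = _aligned(ts, src, model)
                        if arm.endswith("-mp"):
                            choice = inf.mp_select(msa, cands)
                        else:
                            choice, _ = inf.select_topology(
                                msa, cands, model, gamma,
                                estimate_shape=config.estimate_shape,
                            )
                        records.append(
                            dict(
                                alpha=alpha,
                                beta=beta,
                                replicate=rep,
                                arm=arm,
                                correct_weight=float(choice.weights[correct]),
                                lba_weight=float(choice.weights[lba]),
                            )
                        )
                except Exception:
                    logger.exception(
                        "felsenstein replicate failed (a=%s b=%s rep=%d)",
                        alpha, beta, rep,
                    )
                    failures += 1
    reps = pd.DataFrame(records)
    summary = (
        reps.groupby(["alpha", "beta", "arm"])
        .agg(
            correct_frequency=("correct_weight", "mean"),
            lba_frequency=("lba_weight", "mean"),
            n=("replicate", "count"),
        )
        .reset_index()
    )
    return {"replicates": reps, "summary": summary, "failures": failures}


RUNNERS = {
    "divergence": run_divergence,
    "otu_scaling": run_otu_scaling,
    "polytomy": run_polytomy,
    "felsenstein": run_felsenstein,
}


def run_experiment(config: ExperimentConfig, out_dir=None):
    """Dispatch on ``config.experiment``; optionally write TSV tables."""
    if config.experiment not in RUNNERS:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    t0 = time.time()
    result = RUNNERS[config.experiment](config)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in result.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{config.experiment}_{name}.tsv", sep="\t", index=False)
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "failures": result.get("failures", 0),
            "runtime_seconds": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
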