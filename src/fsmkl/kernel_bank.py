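"""Construction of the ordered bank of trace-normalized base kernels.

Each base kernel is a Gram matrix over the training samples computed from one
feature subset of one data type with one kernel function (linear, inhomogeneous
polynomial ``(x.z + 1)^d`` with d in {2, 3}, or Gaussian).  Feature subsets
come from three sources:

* statistical selection — features ranked by the two-sample pooled-variance
  t statistic against the training labels, with nested kernels on the top
  2, 3, ..., N features (N = 15 by default; larger banks buy little and cost
  much);
* pathway membership — columns restricted to the genes of one curated pathway
  (optionally with t-test selection of the top-k members);
* clinical covariates — one kernel per Boolean-encoded covariate.

All Gram matrices are normalized to unit trace so kernels built from
differently scaled data types are commensurable, and the simplex weights the
MKL step learns for them are comparable.  Test-vs-train projections reuse the
training trace constant so the test kernel is consistent with the training one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist

from .data_io import LabelVector, OmicsBlock, PathwayCollection, covariate_of_feature

__all__ = [
    "KernelSpec",
    "BaseKernel",
    "KernelBank",
    "KERNEL_FUNCS",
    "parse_funcs",
    "rank_features_ttest",
    "compute_gram",
    "trace_normalize",
    "median_bandwidth",
    "build_statistical_kernels",
    "build_pathway_kernels",
    "build_clinical_kernels",
    "build_full_block_kernels",
    "assemble_bank",
    "project_bank",
]

#: canonical kernel-function names -> parameter dict
KERNEL_FUNCS = {
    "linear": {},
    "poly2": {"degree": 2},
    "poly3": {"degree": 3},
    "gaussian": {},  # bandwidth filled at build time (median heuristic)
}

DEFAULT_FUNCS = ("linear", "poly2", "poly3")


def parse_funcs(funcs) -> list[str]:
    funcs = list(funcs)
    for f in funcs:
        if f not in KERNEL_FUNCS:
            raise ValueError(f"unknown kernel function {f!r}; "
                             f"choose from {sorted(KERNEL_FUNCS)}")
    return funcs


@dataclass
class KernelSpec:
    """Provenance of one base kernel: where its features came from and how the
    Gram matrix is computed."""

    source_block: str
    feature_ids: tuple[str, ...]
    selection: str          # statistical_top_k | pathway | pathway_top_k |
                            # clinical_covariate | full_block
    selection_detail: dict
    func: str               # linear | poly | gaussian
    func_params: dict = field(default_factory=dict)
    standardize: tuple[tuple, tuple] | None = None  # (means, stds) per column

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ValueError("kernel spec must select at least one feature")
        self.feature_ids = tuple(str(f) for f in self.feature_ids)
        if self.func == "poly" and int(self.func_params.get("degree", 0)) < 2:
            raise ValueError("polynomial kernel needs integer degree >= 2")
        if self.func == "gaussian" and self.func_params.get("bandwidth", 1.0) <= 0:
            raise ValueError("gaussian kernel needs bandwidth > 0")

    def label(self) -> str:
        """Human-readable one-line description used in reports."""
        det = self.selection_detail
        if self.selection == "statistical_top_k":
            what = f"top{det['k']}"
        elif self.selection in ("pathway", "pathway_top_k"):
            what = det["pathway_id"]
            if "k" in det:
                what += f":top{det['k']}"
        elif self.selection == "clinical_covariate":
            what = det["covariate"]
        else:
            what = "all"
        fn = self.func
        if self.func == "poly":
            fn = f"poly{self.func_params['degree']}"
        return f"{self.source_block}/{what}/{fn}"

    def identity(self) -> tuple:
        """Key identifying the same kernel across refits (ignores fold-dependent
        feature lists for statistical selections, which legitimately vary)."""
        det = self.selection_detail
        return (self.source_block, self.selection,
                tuple(sorted((k, str(v)) for k, v in det.items())),
                self.func, str(self.func_params.get("degree", "")))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_ids"] = list(self.feature_ids)
        if self.standardize is not None:
            d["standardize"] = [list(self.standardize[0]), list(self.standardize[1])]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        d = dict(d)
        d["feature_ids"] = tuple(d["feature_ids"])
        if d.get("standardize") is not None:
            d["standardize"] = (tuple(d["standardize"][0]), tuple(d["standardize"][1]))
        return cls(**d)


@dataclass
class BaseKernel:
    """A trace-normalized Gram matrix plus its provenance.

    ``train_trace`` is the pre-normalization trace; test-vs-train projections
    divide by the same constant.
    """

    spec: KernelSpec
    gram: np.ndarray
    train_trace: float

    def validate(self, sym_tol: float = 1e-10, psd_tol: float = 1e-8) -> None:
        g = self.gram
        if not np.allclose(g, g.T, atol=sym_tol, rtol=0):
            raise ValueError(f"kernel {self.spec.label()}: Gram not symmetric")
        if abs(np.trace(g) - 1.0) > 1e-10:
            raise ValueError(f"kernel {self.spec.label()}: trace != 1")
        ev = np.linalg.eigvalsh((g + g.T) / 2)
        if ev[0] < -psd_tol * max(ev[-1], 1e-300):
            raise ValueError(f"kernel {self.spec.label()}: not PSD "
                             f"(min eig {ev[0]:.3e})")


class KernelBank:
    """Ordered collection of base kernels over one common sample set."""

    def __init__(self, kernels: list[BaseKernel], sample_ids: list[str]):
        if not kernels:
            raise ValueError("kernel bank is empty")
        n = len(sample_ids)
        for k in kernels:
            if k.gram.shape != (n, n):
                raise ValueError("all Gram matrices must share the sample dimension")
        self.kernels = list(kernels)
        self.sample_ids = list(sample_ids)
        self._stack: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.kernels)

    def __iter__(self):
        return iter(self.kernels)

    @property
    def specs(self) -> list[KernelSpec]:
        return [k.spec for k in self.kernels]

    def stack(self) -> np.ndarray:
        """All Gram matrices as one (p, n, n) array (cached)."""
        if self._stack is None:
            self._stack = np.stack([k.gram for k in self.kernels])
        return self._stack

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, k in enumerate(self.kernels):
            s = k.spec
            rows.append({
                "index": i, "source": s.source_block, "selection": s.selection,
                "detail": s.label(), "func": s.func,
                "n_features": len(s.feature_ids), "train_trace": k.train_trace,
            })
        return pd.DataFrame(rows)

    def validate(self) -> None:
        for k in self.kernels:
            k.validate()


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def rank_features_ttest(block: OmicsBlock, labels: LabelVector) -> np.ndarray:
    """Feature order by decreasing |t| (two-sample pooled-variance t statistic).

    Ties (and zero-variance features with equal class means, scored 0) keep the
    original column order.  Zero-variance features whose class means differ are
    maximally discriminative and rank first.
    """
    y = labels.y
    if len(np.unique(y)) < 2:
        raise ValueError("ranking requires two classes")
    pos = block.values[y == 1]
    neg = block.values[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("ranking requires >=2 samples per class")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant columns trip scipy's precision warning; degenerate
        # statistics are reassigned explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, _ = stats.ttest_ind(pos, neg, axis=0, equal_var=True)
    t = np.asarray(t, dtype=float)
    diff = pos.mean(axis=0) - neg.mean(axis=0)
    degenerate = ~np.isfinite(t)
    t[degenerate & (np.abs(diff) > 0)] = np.inf
    t[degenerate & (np.abs(diff) == 0)] = 0.0
    return np.argsort(-np.abs(t), kind="stable")


def compute_gram(X: np.ndarray, Z: np.ndarray, func: str,
                 func_params: dict | None = None) -> np.ndarray:
    """Kernel matrix K[i, j] = k(X[i], Z[j]) for the supported kernel functions."""
    func_params = func_params or {}
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(
            f"column mismatch: X has {X.shape[1]} features, Z has {Z.shape[1]}"
        )
    if func == "linear":
        return X @ Z.T
    if func == "poly":
        d = int(func_params["degree"])
        return (X @ Z.T + 1.0) ** d
    if func == "gaussian":
        sigma = float(func_params["bandwidth"])
        if sigma <= 0:
            raise ValueError("gaussian bandwidth must be > 0")
        sq = cdist(X, Z, metric="sqeuclidean")
        return np.exp(-sq / (2.0 * sigma ** 2))
    raise ValueError(f"unknown kernel function {func!r}")


def trace_normalize(gram: np.ndarray) -> np.ndarray:
    """Scale a Gram matrix to unit trace; errors on a degenerate (trace<=0) one."""
    gram = np.asarray(gram, dtype=float)
    tr = float(np.trace(gram))
    if tr <= 1e-300:
        raise ValueError("degenerate kernel: trace is not positive")
    return gram / tr


def median_bandwidth(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance (median heuristic); 1.0 if degenerate."""
    if X.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X)))
    return med if med > 0 else 1.0


def _make_kernel(X: np.ndarray, spec: KernelSpec) -> BaseKernel:
    raw = compute_gram(X, X, spec.func, spec.func_params)
    tr = float(np.trace(raw))
    if tr <= 1e-300:
        raise ValueError("degenerate kernel: trace is not positive")
    return BaseKernel(spec, raw / tr, tr)


def _func_spec(name: str, X: np.ndarray) -> tuple[str, dict]:
    """Resolve a kernel-function name to (func, params), fixing the Gaussian
    bandwidth from the training subset by the median heuristic."""
    if name == "linear":
        return "linear", {}
    if name in ("poly2", "poly3"):
        return "poly", {"degree": int(name[-1])}
    if name == "gaussian":
        return "gaussian", {"bandwidth": median_bandwidth(X)}
    raise ValueError(f"unknown kernel function {name!r}")


# ---------------------------------------------------------------------------
# bank builders
# ---------------------------------------------------------------------------

def build_statistical_kernels(block: OmicsBlock, labels: LabelVector,
                              n_max: int = 15,
                              funcs=DEFAULT_FUNCS) -> list[BaseKernel]:
    """Nested top-k kernels: one per (k, func) for k = 2..n_max.

    Features are ranked by |t| on the given (training) labels; k is capped at
    the block's feature count with a warning.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    funcs = parse_funcs(funcs)
    cap = min(n_max, block.n_features)
    if cap < n_max:
        warnings.warn(
            f"block {block.name!r} has only {block.n_features} features; "
            f"statistical kernels capped at top {cap}",
            stacklevel=2,
        )
    order = rank_features_ttest(block, labels)
    out: list[BaseKernel] = []
    for k in range(2, cap + 1):
        idx = order[:k]
        X = block.values[:, idx]
        fids = tuple(block.features[i] for i in idx)
        for fname in funcs:
            func, params = _func_spec(fname, X)
            spec = KernelSpec(block.name, fids, "statistical_top_k",
                              {"k": k}, func, params)
            out.append(_make_kernel(X, spec))
    return out


def build_pathway_kernels(block: OmicsBlock, pathways: PathwayCollection,
                          funcs=DEFAULT_FUNCS,
                          within_pathway_top_k: int | None = None,
                          labels: LabelVector | None = None,
                          ) -> list[BaseKernel]:
    """One kernel per (pathway, func), columns restricted to member genes.

    Pathways matching fewer than two block features are skipped with a warning.
    With ``within_pathway_top_k``, additional kernels on the t-test top-k
    members (k = 2..min(top_k, members)) are emitted, which requires labels.
    """
    funcs = parse_funcs(funcs)
    if within_pathway_top_k is not None and labels is None:
        raise ValueError("within-pathway selection requires labels")
    feat_pos = {f: i for i, f in enumerate(block.features)}
    out: list[BaseKernel] = []
    for pid, _desc, members in pathways:
        matched = [f for f in block.features if f in set(members)]
        if len(matched) < 2:
            warnings.warn(
                f"pathway {pid!r}: {len(matched)} gene(s) matched in block "
                f"{block.name!r}; skipped",
                stacklevel=2,
            )
            continue
        idx = np.array([feat_pos[f] for f in matched])
        X = block.values[:, idx]
        for fname in funcs:
            func, params = _func_spec(fname, X)
            spec = KernelSpec(block.name, tuple(matched), "pathway",
                              {"pathway_id": pid}, func, params)
            out.append(_make_kernel(X, spec))
        if within_pathway_top_k is not None:
            sub = OmicsBlock(block.name, block.samples, matched, X)
            order = rank_features_ttest(sub, labels)
            for k in range(2, min(within_pathway_top_k, len(matched)) + 1):
                Xk = X[:, order[:k]]
                fids = tuple(matched[i] for i in order[:k])
                for fname in funcs:
                    func, params = _func_spec(fname, Xk)
                    spec = KernelSpec(block.name, fids, "pathway_top_k",
                                      {"pathway_id": pid, "k": k}, func, params)
                    out.append(_make_kernel(Xk, spec))
    return out


def build_clinical_kernels(clin: OmicsBlock,
                           funcs=("linear",)) -> list[BaseKernel]:
    """One kernel per original clinical covariate per kernel function.

    The covariate's indicator (or numeric) columns are grouped back together
    from the encoded block; numeric covariates are standardized to zero mean
    and unit variance on the given (training) samples.  Covariates that are
    constant on these samples yield a degenerate kernel and are dropped with a
    warning.
    """
    funcs = parse_funcs(funcs)
    groups: dict[str, list[int]] = {}
    for j, f in enumerate(clin.features):
        groups.setdefault(covariate_of_feature(f), []).append(j)
    out: list[BaseKernel] = []
    for cov, idx in groups.items():
        X = clin.values[:, idx]
        fids = tuple(clin.features[j] for j in idx)
        standardize = None
        # a lone column not produced by one-hot encoding is a numeric covariate
        if len(idx) == 1 and "=" not in fids[0]:
            mu, sd = float(X.mean()), float(X.std())
            if sd == 0.0:
                warnings.warn(f"clinical covariate {cov!r} is constant; dropped",
                              stacklevel=2)
                continue
            X = (X - mu) / sd
            standardize = ((mu,), (sd,))
        for fname in funcs:
            func, params = _func_spec(fname, X)
            spec = KernelSpec(clin.name, fids, "clinical_covariate",
                              {"covariate": cov}, func, params,
                              standardize=standardize)
            try:
                out.append(_make_kernel(X, spec))
            except ValueError:
                warnings.warn(
                    f"clinical covariate {cov!r}: degenerate kernel dropped",
                    stacklevel=2,
                )
    return out


def build_full_block_kernels(block: OmicsBlock,
                             funcs=DEFAULT_FUNCS) -> list[BaseKernel]:
    """One kernel per function over all of a block's features (no selection)."""
    funcs = parse_funcs(funcs)
    out = []
    for fname in funcs:
        func, params = _func_spec(fname, block.values)
        spec = KernelSpec(block.name, tuple(block.features), "full_block",
                          {}, func, params)
        out.append(_make_kernel(block.values, spec))
    return out


def assemble_bank(blocks: list[OmicsBlock], labels: LabelVector,
                  pathways: PathwayCollection | None = None,
                  clinical_block: OmicsBlock | None = None,
                  use_full_block: bool = False,
                  use_statistical: bool = False, n_max: int = 15,
                  use_pathway: bool = True,
                  within_pathway_top_k: int | None = None,
                  funcs=DEFAULT_FUNCS,
                  clinical_funcs=("linear",)) -> KernelBank:
    """Build the full candidate bank in a deterministic order.

    Order: per block (full-block, statistical, pathway kernels), then clinical
    covariate kernels.  The same inputs and options always yield the same
    kernel indexing.
    """
    kernels: list[BaseKernel] = []
    sample_ids = labels.samples
    for b in blocks:
        if b.samples != sample_ids:
            raise ValueError(f"block {b.name!r} is not aligned with the labels")
        if use_full_block:
            kernels.extend(build_full_block_kernels(b, funcs))
        if use_statistical:
            kernels.extend(build_statistical_kernels(b, labels, n_max, funcs))
        if use_pathway and pathways is not None and len(pathways):
            kernels.extend(build_pathway_kernels(
                b, pathways, funcs, within_pathway_top_k,
                labels if within_pathway_top_k else None))
    if clinical_block is not None:
        if clinical_block.samples != sample_ids:
            raise ValueError("clinical block is not aligned with the labels")
        kernels.extend(build_clinical_kernels(clinical_block, clinical_funcs))
    return KernelBank(kernels, list(sample_ids))


def project_bank(bank: KernelBank, train_blocks: dict[str, OmicsBlock],
                 test_blocks: dict[str, OmicsBlock]) -> np.ndarray:
    """Cross-kernels K(test, train) for every base kernel, as (p, n_test, n_train).

    Each projection reuses the kernel's feature subset, function and parameters
    and divides by the training Gram's pre-normalization trace, so a test set
    equal to the training set reproduces the training Gram exactly.
    """
    mats = []
    for k in bank.kernels:
        s = k.spec
        if s.source_block not in test_blocks:
            raise KeyError(f"no test block named {s.source_block!r}")
        btr = train_blocks[s.source_block]
        bte = test_blocks[s.source_block]
        Xtr = btr.values[:, btr.feature_index(list(s.feature_ids))]
        Xte = bte.values[:, bte.feature_index(list(s.feature_ids))]
        if s.standardize is not None:
            mu = np.asarray(s.standardize[0], dtype=float)
            sd = np.asarray(s.standardize[1], dtype=float)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        mats.append(compute_gram(Xte, Xtr, s.func, s.func_params) / k.train_trace)
    return np.stack(mats)
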