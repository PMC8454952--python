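"""Endpoint classification, clustering, secondary structure, contact maps
and per-contact frustration for refolding simulations.

Classification follows the Q_W convention: completely refolded structures
score high (folded at Q_W >= 0.7 by default), a partially formed state with
only the core strands/helices sits in the 0.4-0.6 band (intermediate), and
anything lower is misfolded or unfolded; values in the (0.6, 0.7) gap take
the nearest class with a low-confidence flag.  Frustration is scored per
native contact as a z-score of its energy against identity-shuffled decoys
(minimally frustrated above +0.78, highly frustrated below -1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import beta as beta_dist

from . import params
from .chain import CoarseChain, ReferenceState, StructureError
from .cv import best_fit_rmsd, compute_qw
from .energy import DEFAULT_CONSTANTS, ModelConstants

#: frustration-index thresholds (frustratometer convention)
FRUSTRATION_MINIMAL = 0.78
FRUSTRATION_HIGH = -1.0


@dataclass
class ClassificationThresholds:
    folded_min: float = 0.7
    intermediate_lo: float = 0.4
    intermediate_hi: float = 0.6
    variant: str = "all_pairs"


@dataclass
class FoldClass:
    label: str                   # folded | intermediate | misfolded_or_unfolded
    q_w: float
    variant: str
    reference: str
    low_confidence: bool = False


def classify_endpoint(chain: CoarseChain, ref: ReferenceState,
                      thresholds: ClassificationThresholds | None = None
                      ) -> FoldClass:
    """Classify a final structure by its Q_W against the reference fold."""
    t = thresholds or ClassificationThresholds()
    qw = compute_qw(chain, ref, t.variant)
    low_conf = False
    if qw >= t.folded_min:
        label = "folded"
    elif qw > t.intermediate_hi:
        # gap between bands: nearest class, flagged
        low_conf = True
        mid = 0.5 * (t.intermediate_hi + t.folded_min)
        label = "folded" if qw >= mid else "intermediate"
    elif qw >= t.intermediate_lo:
        label = "intermediate"
    else:
        label = "misfolded_or_unfolded"
    return FoldClass(label=label, q_w=qw, variant=t.variant,
                     reference=ref.name, low_confidence=low_conf)


@dataclass
class ClusterResult:
    labels: np.ndarray            # cluster id per structure (0-based, ordered
                                  # by first occurrence)
    medoids: dict[int, int]       # cluster id -> member structure index
    threshold: float
    rmsd_matrix: np.ndarray


def cluster_endpoints(structures: list[CoarseChain],
                      threshold: float = 2.0) -> ClusterResult:
    """Complete-linkage clustering on the pairwise best-fit CA RMSD matrix.

    Cluster ids are renumbered by the lowest member index (deterministic);
    the medoid minimizes its summed RMSD to cluster members, ties broken by
    the lowest structure index.
    """
    m = len(structures)
    if m < 1:
        raise StructureError("need at least one structure")
    dmat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dmat[i, j] = dmat[j, i] = best_fit_rmsd(structures[i],
                                                    structures[j])
    if m == 1:
        raw = np.array([1])
    else:
        raw = fcluster(linkage(squareform(dmat, checks=False),
                               method="complete"),
                       t=threshold, criterion="distance")
    labels = np.empty(m, int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]
    medoids = {}
    for c in sorted(set(labels)):
        members = np.where(labels == c)[0]
        sums = dmat[np.ix_(members, members)].sum(axis=1)
        medoids[c] = int(members[np.argmin(sums)])
    return ClusterResult(labels=labels, medoids=medoids, threshold=threshold,
                         rmsd_matrix=dmat)


def assign_secondary_structure(chain: CoarseChain) -> str:
    """Per-residue H/E/C string from CA-trace geometry.

    A residue is locally helical when the (i-1, i+1) distance and the
    accompanying (i, i+3) distances sit in the helical bands, locally
    extended when they sit in the strand bands; helices and strands require
    at least 3 consecutive qualifying residues, everything else is coil.
    """
    ca = chain.ca_xyz
    n = len(ca)
    d13 = np.full(n, np.nan)
    d13[1:n - 1] = np.linalg.norm(ca[2:] - ca[:-2], axis=1)
    d14 = np.full(n, np.nan)
    d14[:n - 3] = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
    d15 = np.full(n, np.nan)
    d15[:n - 4] = np.linalg.norm(ca[4:] - ca[:-4], axis=1)

    raw = []
    for i in range(n):
        label = "C"
        if not np.isnan(d13[i]):
            near14 = [d14[j] for j in (i - 2, i - 1, i) if 0 <= j < n - 3]
            # the window of d(i, i+4) centered on this residue (clamped at
            # the termini): strands are straight over 5 residues, turns are
            # not even when their local d13 looks extended
            c15 = min(max(i - 2, 0), n - 5)
            if 4.8 <= d13[i] <= 5.9 and any(4.3 <= d <= 5.9 for d in near14):
                label = "H"
            elif (6.15 <= d13[i] <= 7.3 and any(d >= 8.6 for d in near14)
                  and d15[c15] >= 12.4):
                label = "E"
        raw.append(label)
    # enforce minimum run length of 3
    out = list(raw)
    i = 0
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        if raw[i] in "HE" and j - i < 3:
            for k in range(i, j):
                out[k] = "C"
        i = j
    return "".join(out)


def interface_contact_map(chain: CoarseChain, group_a: tuple[int, int],
                          group_b: tuple[int, int],
                          cutoff: float = 9.5) -> set[tuple[int, int]]:
    """Cross-group CA contact pairs (1-based residue ids, a < b side kept)."""
    a0, a1 = group_a
    b0, b1 = group_b
    if not (a1 < b0 or b1 < a0):
        raise StructureError("interface groups overlap")
    ca = chain.ca_xyz
    out = set()
    for i in range(a0 - 1, a1):
        for j in range(b0 - 1, b1):
            if np.linalg.norm(ca[i] - ca[j]) <= cutoff:
                out.add((i + 1, j + 1))
    return out


def contact_map_difference(map_a: set, map_b: set) -> dict[str, set]:
    """Contacts unique to each structure and shared by both."""
    return {"only_a": map_a - map_b, "only_b": map_b - map_a,
            "shared": map_a & map_b}


@dataclass
class FrustrationReport:
    contacts: list[tuple[int, int]]        # 1-based residue pairs
    f_index: np.ndarray
    classes: list[str]                     # minimal | neutral | high
    minimal_per_residue: np.ndarray
    high_per_residue: np.ndarray
    n_decoys: int
    seed: int
    degenerate: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.minimal_per_residue)
        return pd.DataFrame({
            "residue": np.arange(1, n + 1),
            "minimally_frustrated": self.minimal_per_residue,
            "highly_frustrated": self.high_per_residue,
        })


def _contact_pair_energy(gamma: np.ndarray, scale2: float, ti: int, tj: int,
                         r: np.ndarray | float, w1, w2) -> np.ndarray:
    from ._kernels import _well
    r_arr = np.atleast_1d(np.asarray(r, float))
    th1 = np.array([_well(x, *w1)[0] for x in r_arr])
    th2 = np.array([_well(x, *w2)[0] for x in r_arr])
    return gamma[ti, tj] * (th1 + scale2 * th2)


def frustration_scan(chain: CoarseChain, n_decoys: int = 1000, seed: int = 0,
                     constants: ModelConstants = DEFAULT_CONSTANTS,
                     contact_cutoff: float = 9.5,
                     min_separation: int = 3,
                     resample_distance: bool = False) -> FrustrationReport:
    """Per-contact frustration z-scores with identity-shuffled decoys.

    For each native contact (CB pair within the pair-potential range and CA
    distance <= cutoff), decoys redraw the two residue identities from the
    chain's composition (mutational scheme); with ``resample_distance`` the
    pair distance is additionally redrawn uniformly within the contact
    wells.  F_ij = (<E_decoy> - E_native) / sd(E_decoy).  A homopolymer
    under the pure identity scheme has sd = 0 everywhere: such contacts are
    marked neutral with the degenerate flag set.
    """
    rng = np.random.default_rng(seed)
    types = params.residue_type_indices(chain.sequence)
    gamma = constants.contact_scale * params.contact_matrix()
    w1 = tuple(constants.contact_well1)
    w2 = tuple(constants.contact_well2)
    n = chain.n_residues
    contacts, f_vals, classes, degenerate = [], [], [], []
    r_lo, r_hi = w1[0], w2[3]
    for i in range(n):
        for j in range(i + min_separation, n):
            r_ca = np.linalg.norm(chain.ca_xyz[i] - chain.ca_xyz[j])
            r_cb = np.linalg.norm(chain.cb_xyz[i] - chain.cb_xyz[j])
            if r_ca > contact_cutoff or not (r_lo < r_cb < r_hi):
                continue
            e_nat = float(_contact_pair_energy(
                gamma, constants.contact_second_scale,
                types[i], types[j], r_cb, w1, w2)[0])
            ti = rng.choice(types, n_decoys)
            tj = rng.choice(types, n_decoys)
            if resample_distance:
                rr = rng.uniform(r_lo, r_hi, n_decoys)
            else:
                rr = np.full(n_decoys, r_cb)
            e_dec = np.array([
                _contact_pair_energy(gamma, constants.contact_second_scale,
                                     a, b, r, w1, w2)[0]
                for a, b, r in zip(ti, tj, rr)])
            sd = float(e_dec.std())
            contacts.append((i + 1, j + 1))
            if sd <= 1e-12 * max(1.0, abs(float(e_dec.mean()))):
                f_vals.append(0.0)
                classes.append("neutral")
                degenerate.append(True)
                continue
            f = (float(e_dec.mean()) - e_nat) / sd
            f_vals.append(f)
            degenerate.append(False)
            if f > FRUSTRATION_MINIMAL:
                classes.append("minimal")
            elif f < FRUSTRATION_HIGH:
                classes.append("high")
            else:
                classes.append("neutral")
    minimal = np.zeros(n, int)
    high = np.zeros(n, int)
    for (i, j), cl in zip(contacts, classes):
        if cl == "minimal":
            minimal[i - 1] += 1
            minimal[j - 1] += 1
        elif cl == "high":
            high[i - 1] += 1
            high[j - 1] += 1
    return FrustrationReport(contacts=contacts, f_index=np.array(f_vals),
                             classes=classes, minimal_per_residue=minimal,
                             high_per_residue=high, n_decoys=n_decoys,
                             seed=seed, degenerate=np.array(degenerate, bool))


def binomial_ci(k: int, m: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson (exact binomial) confidence interval for k/m."""
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, m - k + 1))
    hi = 1.0 if k == m else float(beta_dist.ppf(1 - alpha / 2, k + 1, m - k))
    return lo, hi


def refolding_summary(replicas, ref: ReferenceState,
                      thresholds: ClassificationThresholds | None = None,
                      cluster_threshold: float = 2.0
                      ) -> tuple[pd.DataFrame, dict]:
    """One row per annealing run + aggregate refolding efficiency.

    ``replicas`` is a list of objects with ``trajectory.final_chain`` and
    ``seed`` (as produced by the annealing protocol) or plain chains.
    """
    chains, seeds = [], []
    for rep in replicas:
        if isinstance(rep, CoarseChain):
            chains.append(rep)
            seeds.append(None)
        else:
            chains.append(rep.trajectory.final_chain)
            seeds.append(rep.seed)
    if not chains:
        raise StructureError("no runs to summarize")
    clusters = cluster_endpoints(chains, cluster_threshold)
    rows = []
    for idx, chain in enumerate(chains):
        fc = classify_endpoint(chain, ref, thresholds)
        rows.append({
            "run": idx, "seed": seeds[idx], "final_q_w": fc.q_w,
            "fold_class": fc.label, "low_confidence": fc.low_confidence,
            "cluster": int(clusters.labels[idx]),
            "secondary_structure": assign_secondary_structure(chain),
        })
    table = pd.DataFrame(rows)
    k = int((table["fold_class"] == "folded").sum())
    m = len(table)
    lo, hi = binomial_ci(k, m)
    stats = {"n_runs": m, "n_folded": k, "efficiency": k / m,
             "ci95": (lo, hi), "cluster_sizes":
             table.groupby("cluster").size().to_dict()}
    return table, stats
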