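"""Hyper-/hypomethylation scoring of tumors against a normal reference.

Four steps: (1) group CpG probes into bounded regional clusters per
chromosome and region class (CpG island vs open sea), (2) average beta
values within each cluster, (3) express each tumor's cluster methylation as
a z-value against the normal-sample mean and standard deviation, (4)
summarise each tumor as the mean positive z over CGI clusters (the
hypermethylation score) and the mean negative z over open-sea clusters
(the hypomethylation score, <= 0 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import GcRepairError, MethylationData

MAX_WIDTH = 1500   # bp, largest allowed cluster span
MAX_GAP = 500      # bp, largest allowed gap between neighbouring probes
SD_FLOOR = 1e-6    # normal-reference sd below this -> cluster unusable

CGI, OPEN_SEA = "CGI", "open_sea"


@dataclass
class ProbeCluster:
    """A run of same-class probes bounded in width and inter-probe gap."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    probes: list[str]
    region_class: str

    @property
    def width(self) -> int:
        return self.end - self.start


def build_clusters(annotation: pd.DataFrame, max_width: int = MAX_WIDTH,
                   max_gap: int = MAX_GAP,
                   promoter_only: bool = False) -> list[ProbeCluster]:
    """Greedy left-to-right clustering of CGI and open-sea probes.

    Probes are sorted per chromosome and region class; the current cluster
    is extended while the next probe is within ``max_gap`` of the previous
    one *and* within ``max_width`` of the cluster start, otherwise a new
    cluster begins.  Singletons are allowed.  Probes with region class
    'other' are dropped.  With ``promoter_only`` and a ``promoter`` column,
    CGI probes are restricted to promoter-associated ones.
    """
    ann = annotation[annotation["region_class"].isin([CGI, OPEN_SEA])].copy()
    if promoter_only and "promoter" in ann.columns:
        drop = (ann["region_class"] == CGI) & ~ann["promoter"].astype(bool)
        ann = ann[~drop]
    ann = ann.sort_values(["chrom", "region_class", "pos"],
                          kind="stable")
    clusters: list[ProbeCluster] = []
    for (chrom, rclass), grp in ann.groupby(["chrom", "region_class"],
                                            sort=True):
        positions = grp["pos"].to_numpy(dtype=int)
        probes = list(grp.index)
        start_i = 0
        for i in range(1, len(positions) + 1):
            end_of_run = (
                i == len(positions)
                or positions[i] - positions[i - 1] > max_gap
                or positions[i] - positions[start_i] > max_width
            )
            if end_of_run:
                member = probes[start_i:i]
                lo, hi = int(positions[start_i]), int(positions[i - 1])
                clusters.append(ProbeCluster(
                    cluster_id=f"{chrom}:{lo}-{hi}:{rclass}",
                    chrom=str(chrom), start=lo, end=hi,
                    probes=member, region_class=rclass))
                start_i = i
    return clusters


def cluster_beta(meth: MethylationData,
                 clusters: list[ProbeCluster]) -> pd.DataFrame:
    """Mean beta of member probes, per cluster and sample (NaN-excluded
    means; a cluster with no observed probe in a sample stays NaN)."""
    rows = []
    for cl in clusters:
        if not cl.probes:
            raise GcRepairError(f"cluster {cl.cluster_id} has no probes")
        missing = [p for p in cl.probes if p not in meth.beta.index]
        if missing:
            raise GcRepairError(
                f"cluster {cl.cluster_id}: probes missing from beta "
                f"matrix: {missing[:5]}")
        rows.append(meth.beta.loc[cl.probes].mean(axis=0, skipna=True))
    return pd.DataFrame(rows, index=[cl.cluster_id for cl in clusters])


def relative_methylation(tumor_cb: pd.DataFrame, normal_cb: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-like relative methylation of each tumor cluster value against the
    normal reference (sample sd, n-1 denominator).

    Returns (z matrix, reference frame with per-cluster mean/sd).  Clusters
    whose normal sd is below the floor become NaN and drop out downstream.
    """
    if normal_cb.shape[1] < 3:
        raise GcRepairError(
            f"need >= 3 normal samples, got {normal_cb.shape[1]}")
    common = tumor_cb.index.intersection(normal_cb.index)
    mean = normal_cb.loc[common].mean(axis=1)
    sd = normal_cb.loc[common].std(axis=1, ddof=1)
    usable = sd >= SD_FLOOR
    z = tumor_cb.loc[common].sub(mean, axis=0).div(sd.where(usable), axis=0)
    ref = pd.DataFrame({"mean": mean, "sd": sd, "usable": usable})
    return z, ref


def hyper_hypo_scores(rel: pd.DataFrame, clusters: list[ProbeCluster],
                      clip_mean: bool = False) -> pd.DataFrame:
    """Per-tumor hyper- and hypomethylation scores.

    hyper = mean of the *positive* z values over CGI clusters;
    hypo = mean of the *negative* z values over open-sea clusters.
    With ``clip_mean`` the mean runs over all clusters of the class with z
    clipped at zero instead (the alternative reading of the aggregation).
    An empty selection yields NaN.
    """
    by_class = {CGI: [], OPEN_SEA: []}
    for cl in clusters:
        if cl.cluster_id in rel.index:
            by_class[cl.region_class].append(cl.cluster_id)
    out = pd.DataFrame(index=rel.columns,
                       columns=["hyper_score", "hypo_score"], dtype=float)
    cgi = rel.loc[by_class[CGI]]
    sea = rel.loc[by_class[OPEN_SEA]]
    if clip_mean:
        out["hyper_score"] = cgi.clip(lower=0).mean(axis=0, skipna=True)
        out["hypo_score"] = sea.clip(upper=0).mean(axis=0, skipna=True)
    else:
        out["hyper_score"] = cgi.where(cgi > 0).mean(axis=0, skipna=True)
        out["hypo_score"] = sea.where(sea < 0).mean(axis=0, skipna=True)
    return out
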