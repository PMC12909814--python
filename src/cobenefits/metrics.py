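"""Transboundary inequality metrics.

Three metrics summarize how co-benefits (deaths avoided, or exposure
changes) are exchanged across borders:

* **TF** — transboundary fraction: the share of a receptor's total
  co-benefits attributable to emission changes outside its territory.
  Defined for single countries, for groups/regions (intra-group foreign
  contributions count as internal), and globally (sum of external over sum
  of total); an unweighted all-country mean is reported as a distinct
  statistic.
* **EXC** — exchange: co-benefits realized in receptor n from emission
  changes in source m; the diagonal is the domestic term and the net
  exchange is the antisymmetric pair difference.
* **TEC** — contribution to total co-benefits exchanged: EXC(m, n) over
  the gross pair exchange; 0.5 is balance, values above 0.5 mean m
  contributes more.

Fractional border cells contribute to "inside" and "outside" sums in
proportion to their mask fraction, consistent with the source-country
aggregation, so TF, EXC and the receptor totals satisfy an exact
conservation identity: domestic + sum of foreign exchanges + unattributed
equals the receptor total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import ContributionMatrix
from .errors import ValidationError
from .masks import UNATTRIBUTED, CountryMaskSet

FLAG_OK = "ok"
FLAG_UNDEFINED = "undefined"
FLAG_OUT_OF_RANGE = "out_of_range"


def transboundary_fraction(
    contrib, masks: CountryMaskSet, receptor: str | list[str]
) -> tuple[float, str]:
    """TF for one receptor country or a group treated as one territory.

    ``contrib`` is any per-cell contribution object (deaths avoided by
    default, exposure optionally) with ``receptors``/``values``/``grid``.
    For a group, every member must be a receptor; external means outside
    the union of member territories. Returns (tf, flag): flag is
    ``undefined`` when the total is zero (tf = NaN) and ``out_of_range``
    when mixed-sign contributions push the raw ratio outside [0, 1].
    """
    members = [receptor] if isinstance(receptor, str) else list(receptor)
    frac = masks.group_fraction(members)
    total = 0.0
    internal = 0.0
    for c in members:
        if c not in contrib.receptors:
            raise ValidationError(f"receptor {c!r} not in contributions")
        fld = contrib.values[contrib.receptors.index(c)]
        total += float(fld.sum())
        internal += float((frac * fld).sum())
    if total == 0.0:
        return float("nan"), FLAG_UNDEFINED
    tf = (total - internal) / total
    flag = FLAG_OK if 0.0 - 1e-12 <= tf <= 1.0 + 1e-12 else FLAG_OUT_OF_RANGE
    return tf, flag


def tf_table(contrib, masks: CountryMaskSet) -> pd.DataFrame:
    """Per-country TF table with external/domestic/total decomposition."""
    rows = []
    for c in contrib.receptors:
        if c not in masks.country_ids:
            continue
        fld = contrib.values[contrib.receptors.index(c)]
        total = float(fld.sum())
        domestic = float((masks.fraction(c) * fld).sum())
        tf, flag = transboundary_fraction(contrib, masks, c)
        rows.append(
            {
                "receptor": c,
                "total": total,
                "domestic": domestic,
                "external": total - domestic,
                "tf": tf,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows).set_index("receptor")


def global_tf(contrib, masks: CountryMaskSet) -> float:
    """Sum of all countries' external co-benefits over the sum of totals."""
    t = tf_table(contrib, masks)
    total = t["total"].sum()
    if total == 0:
        return float("nan")
    return float(t["external"].sum() / total)


def mean_country_tf(contrib, masks: CountryMaskSet) -> float:
    """Unweighted mean TF over countries where TF is defined and in range."""
    t = tf_table(contrib, masks)
    ok = t.loc[t["flag"] == FLAG_OK, "tf"]
    return float(ok.mean()) if len(ok) else float("nan")


def exchange(matrix: ContributionMatrix, source: str, receptor: str) -> float:
    """EXC(source, receptor): co-benefits in the receptor from the source.

    ``exchange(m, m)`` is the domestic term; pairwise reporting excludes
    it, as does the unattributed pseudo-source.
    """
    return matrix.lookup(source, receptor)


def net_exchange(matrix: ContributionMatrix, m: str, n: str) -> float:
    """EXC(m, n) - EXC(n, m); antisymmetric by construction."""
    return exchange(matrix, m, n) - exchange(matrix, n, m)


def tec(matrix: ContributionMatrix, m: str, n: str) -> tuple[float, str]:
    """Share of the pair's gross exchanged co-benefits contributed by m.

    Undefined (NaN, flagged) when the gross exchange is zero. The two
    orientations of a pair are computed from a single division (the
    lexicographically smaller label gets the ratio, the other its
    complement) so that tec(m, n) + tec(n, m) == 1 holds exactly.
    """
    if m == n:
        raise ValidationError("TEC needs two distinct countries")
    if m > n:
        t, f = tec(matrix, n, m)
        return (1.0 - t if f == FLAG_OK else t), f
    a = exchange(matrix, m, n)
    b = exchange(matrix, n, m)
    gross = a + b
    if gross == 0.0:
        return float("nan"), FLAG_UNDEFINED
    t = a / gross
    flag = FLAG_OK if (a >= 0 and b >= 0) else FLAG_OUT_OF_RANGE
    return t, flag


def exchange_table(matrix: ContributionMatrix) -> pd.DataFrame:
    """Long-format country-pair table of EXC, net exchange and TEC.

    Diagonal (domestic) entries and the unattributed pseudo-source are
    excluded; each ordered pair (m, n), m != n, gets one row.
    """
    countries = [s for s in matrix.sources if s != UNATTRIBUTED]
    rows = []
    for m in countries:
        for n in countries:
            if m == n or n not in matrix.receptors:
                continue
            t, flag = tec(matrix, m, n)
            rows.append(
                {
                    "source": m,
                    "receptor": n,
                    "exc": exchange(matrix, m, n),
                    "net_exc": net_exchange(matrix, m, n),
                    "tec": t,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def stratified_summary(
    tf: pd.Series, strata: pd.Series, k: int
) -> pd.DataFrame:
    """Mean TF over the bottom-k and top-k countries by a stratum variable.

    ``tf`` and ``strata`` (e.g. HDI or GDP rank) are indexed by country id.
    Sorting is stable with the country id as tiebreak so the selection is
    deterministic.
    """
    common = tf.index.intersection(strata.index)
    if k <= 0 or k > len(common):
        raise ValidationError(f"k={k} out of range for {len(common)} countries")
    order = sorted(common, key=lambda c: (strata[c], c))
    bottom, top = order[:k], order[-k:]
    return pd.DataFrame(
        [
            {"group": f"bottom_{k}", "mean_tf": float(tf.loc[bottom].mean()),
             "members": ",".join(bottom)},
            {"group": f"top_{k}", "mean_tf": float(tf.loc[top].mean()),
             "members": ",".join(top)},
        ]
    ).set_index("group")


def relative_change(a: pd.Series, b: pd.Series) -> pd.Series:
    """(b - a) / a elementwise, for scenario-to-scenario TF comparisons."""
    return (b - a) / a


@dataclass
class InequalityReport:
    """Bundle of the inequality metrics for one scenario and bound."""

    scenario_id: str
    bound: str
    tf: pd.DataFrame                 # per-country table from tf_table()
    regional_tf: pd.DataFrame        # per-region TF (group semantics)
    pairs: pd.DataFrame              # from exchange_table()
    strata: pd.DataFrame             # from stratified_summary()
    global_tf: float
    mean_country_tf: float
    total_deaths_avoided: float

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "scenario": self.scenario_id,
                "bound": self.bound,
                "total_deaths_avoided": self.total_deaths_avoided,
                "global_tf": self.global_tf,
                "mean_country_tf": self.mean_country_tf,
            }
        )


def build_report(
    deaths, matrix: ContributionMatrix, masks: CountryMaskSet, k: int | None = None
) -> InequalityReport:
    """Assemble the full inequality report from per-cell deaths avoided."""
    tf = tf_table(deaths, masks)
    regions = []
    for region in masks.regions:
        members = [c for c in masks.region_members(region) if c in deaths.receptors]
        if not members:
            continue
        val, flag = transboundary_fraction(deaths, masks, members)
        regions.append({"region": region, "tf": val, "flag": flag})
    regional = pd.DataFrame(regions).set_index("region") if regions else pd.DataFrame()
    pairs = exchange_table(matrix)
    table = masks.table.set_index("country_id")
    kk = k if k is not None else max(1, min(20, masks.n_countries // 2))
    strata = stratified_summary(tf["tf"], table["hdi"], kk)
    return InequalityReport(
        scenario_id=getattr(deaths, "scenario_id", ""),
        bound=getattr(deaths, "bound", "central"),
        tf=tf,
        regional_tf=regional,
        pairs=pairs,
        strata=strata,
        global_tf=global_tf(deaths, masks),
        mean_country_tf=mean_country_tf(deaths, masks),
        total_deaths_avoided=float(deaths.values.sum()),
    )
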