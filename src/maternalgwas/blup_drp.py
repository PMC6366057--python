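"""BLUP breeding values with reliabilities, and de-regressed proofs.

The mixed-model equations of the maternal animal model are solved at
the REML estimates for *all* pedigree animals (an animal model yields
breeding values for non-phenotyped relatives too, which is why more
animals carry a maternal proof than a direct one). Reliabilities come
from prediction-error variances on the inverse coefficient-matrix
diagonal.

Deregression strips the parent-average and shrinkage out of an EBV,
producing a pseudo-phenotype (DRP) whose information content is the
animal's own. It is defined as the exact inversion of a two-source
normal blending system: the EBV is the posterior mean combining the
parent-average prior (reliability ``r2_PA = (r2_sire + r2_dam)/4``)
with own information worth ``z`` effective records
(``lambda_g = (1 - h2)/h2`` residual-to-genetic variance units).
Writing ``q = 1/(1 - r2)``:

    z / lambda_g = q_i - q_PA                  (own information)
    DRP          = (q_i EBV - q_PA PA) / (q_i - q_PA)
    r2_DRP       = (q_i - q_PA) / (q_i - q_PA + 1)
    weight       = (1 - h2) / ((c + (1 - r2_DRP)/r2_DRP) h2)

Feeding DRP and its information back through the forward blending
equations reproduces (EBV, r2) exactly; that identity is the module's
correctness criterion.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io_formats import FOUNDER, Pedigree, ValidationError
from .kinship import build_A_inverse
from .reml import ModelFit

logger = logging.getLogger(__name__)

__all__ = ["BreedingValueSet", "DRPTable", "solve_mme", "deregress",
           "filter_drp", "blend"]


@dataclasses.dataclass
class BreedingValueSet:
    """Direct and maternal EBVs with reliabilities for all pedigree animals."""

    values: pd.DataFrame   # index animal: ebv_direct, ebv_maternal,
                           # rel_direct, rel_maternal
    fixed_solutions: np.ndarray
    var_direct: float
    var_maternal: float


@dataclasses.dataclass
class DRPTable:
    """De-regressed proofs with information weights.

    ``kept`` marks rows surviving the weight filter; dropped animals
    (own information non-positive) are absent entirely.
    """

    table: pd.DataFrame    # animal, drp, weight, reliability, kept
    effect: str            # "direct" or "maternal"
    h2: float

    def kept(self) -> pd.DataFrame:
        return self.table[self.table["kept"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

def solve_mme(model_fit: ModelFit) -> BreedingValueSet:
    """Solve the maternal-model MME at the REML estimates.

    Unknowns: fixed effects, direct breeding value and maternal
    breeding value for every pedigree animal, and a permanent-
    environment effect per dam with records. Reliabilities are
    ``1 - PEV / sigma2`` from the direct inverse of the coefficient
    matrix (exact at desk scale).
    """
    vc = model_fit.vc.estimates
    s_u, s_m, s_pe, s_e = (vc["direct"], vc["maternal"],
                           vc["maternal_pe"], vc["residual"])
    s_um = vc.get("cov_direct_maternal", 0.0)

    ped = model_fit.pedigree
    order = ped.animals
    pos = {a: i for i, a in enumerate(order)}
    N = len(order)
    n = len(model_fit.y)
    X = model_fit.X
    p = X.shape[1]
    ai = np.array([pos[a] for a in model_fit.animal_ids])
    di = np.array([pos[d] for d in model_fit.dam_ids])
    dams_with_records = list(dict.fromkeys(model_fit.dam_ids))
    q = len(dams_with_records)
    pe_pos = {d: i for i, d in enumerate(dams_with_records)}
    si = np.array([pe_pos[d] for d in model_fit.dam_ids])

    Zu = np.zeros((n, N)); Zu[np.arange(n), ai] = 1.0
    Zm = np.zeros((n, N)); Zm[np.arange(n), di] = 1.0
    S = np.zeros((n, q)); S[np.arange(n), si] = 1.0
    W = np.hstack([X, Zu, Zm, S])

    Ainv = build_A_inverse(ped).matrix
    G0 = np.array([[s_u, s_um], [s_um, s_m]])
    G0inv = np.linalg.inv(G0)
    dim = p + 2 * N + q
    C = (W.T @ W) / s_e
    Sigma_inv = np.zeros((dim, dim))
    Sigma_inv[p:p + N, p:p + N] = G0inv[0, 0] * Ainv
    Sigma_inv[p:p + N, p + N:p + 2 * N] = G0inv[0, 1] * Ainv
    Sigma_inv[p + N:p + 2 * N, p:p + N] = G0inv[1, 0] * Ainv
    Sigma_inv[p + N:p + 2 * N, p + N:p + 2 * N] = G0inv[1, 1] * Ainv
    Sigma_inv[p + 2 * N:, p + 2 * N:] = np.eye(q) / s_pe
    C += Sigma_inv
    rhs = (W.T @ model_fit.y) / s_e

    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValidationError("singular MME coefficient matrix") from err
    sol = Cinv @ rhs
    beta = sol[:p]
    u_hat = sol[p:p + N]
    m_hat = sol[p + N:p + 2 * N]
    pev_u = np.diag(Cinv)[p:p + N]
    pev_m = np.diag(Cinv)[p + N:p + 2 * N]
    rel_u = np.clip(1.0 - pev_u / s_u, 0.0, 1.0 - 1e-12)
    rel_m = np.clip(1.0 - pev_m / s_m, 0.0, 1.0 - 1e-12)

    values = pd.DataFrame({
        "ebv_direct": u_hat, "ebv_maternal": m_hat,
        "rel_direct": rel_u, "rel_maternal": rel_m,
    }, index=pd.Index(order, name="animal"))
    return BreedingValueSet(values, beta, s_u, s_m)


# ---------------------------------------------------------------------------
# deregression
# ---------------------------------------------------------------------------

def blend(drp, r2_drp, pa, r2_pa):
    """Forward blending: combine a DRP-style own source with a
    parent-average prior into (EBV, reliability).

    The inverse of :func:`deregress`'s core transform; used as the
    self-consistency oracle.
    """
    q_pa = 1.0 / (1.0 - r2_pa)
    z_rel = r2_drp / (1.0 - r2_drp)     # z / lambda_g
    q_i = q_pa + z_rel
    ebv = (q_pa * pa + z_rel * drp) / q_i
    r2 = 1.0 - 1.0 / q_i
    return ebv, r2


def deregress(bvs: BreedingValueSet, ped: Pedigree, h2: float,
              c: float = 0.5, effect: str = "direct") -> DRPTable:
    """De-regress EBVs into pseudo-phenotypes with information weights.

    ``effect`` selects the direct or maternal EBV/reliability columns;
    the machinery is identical. ``c`` is the fraction of genetic
    variance assumed not captured by markers in the weight formula.
    Animals whose own information is non-positive (reliability not
    above the parent-average reliability) are dropped with a log
    message.
    """
    if not 0 < h2 < 1:
        raise ValidationError("h2 must be in (0, 1)")
    col_ebv = f"ebv_{effect}"
    col_rel = f"rel_{effect}"
    vals = bvs.values
    rec = ped.records.set_index("animal")

    rows, dropped = [], 0
    for animal, row in vals.iterrows():
        sire = rec.loc[animal, "sire"] if animal in rec.index else FOUNDER
        dam = rec.loc[animal, "dam"] if animal in rec.index else FOUNDER
        pa, r2_pa = 0.0, 0.0
        for parent in (sire, dam):
            if parent != FOUNDER and parent in vals.index:
                pa += 0.5 * vals.loc[parent, col_ebv]
                r2_pa += 0.25 * vals.loc[parent, col_rel]
        r2_i = float(row[col_rel])
        own = 1.0 / (1.0 - r2_i) - 1.0 / (1.0 - r2_pa)
        if own <= 1e-12:
            dropped += 1
            continue
        q_i = 1.0 / (1.0 - r2_i)
        q_pa = 1.0 / (1.0 - r2_pa)
        drp = (q_i * float(row[col_ebv]) - q_pa * pa) / own
        r2_drp = own / (own + 1.0)
        weight = (1.0 - h2) / ((c + (1.0 - r2_drp) / r2_drp) * h2)
        rows.append({"animal": animal, "drp": drp, "weight": weight,
                     "reliability": r2_drp})
    if dropped:
        logger.warning(
            "%d animals dropped: own information non-positive "
            "(reliability not above parent average)", dropped)
    table = pd.DataFrame(rows, columns=["animal", "drp", "weight",
                                        "reliability"])
    table["kept"] = True
    return DRPTable(table, effect, h2)


def filter_drp(drp: DRPTable, w_min: float = 0.2) -> DRPTable:
    """Flag rows with weight not exceeding ``w_min`` as excluded
    (strict ``weight > w_min`` keeps)."""
    table = drp.table.copy()
    table["kept"] = table["weight"] > w_min
    if len(table) and not table["kept"].any():
        logger.warning("every DRP record excluded by the weight filter")
    return DRPTable(table, drp.effect, drp.h2)
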