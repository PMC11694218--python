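"""Cartesian point-multipole interaction tensors through quadrupole-quadrupole.

Moments follow the Buckingham convention: charge q (e), dipole mu (e Å), and
traceless quadrupole Theta = 1/2 sum q (3 r r - r^2 I) (e Å^2).  With
T^(n) = grad^n (1/R), R the vector from site A to site B, the interaction
energy is

    U = q_A q_B T
        + T_a (q_A mu_Ba - mu_Aa q_B)
        + T_ab (q_A Theta_Bab/3 + Theta_Aab q_B/3 - mu_Aa mu_Bb)
        + T_abc (Theta_Aab mu_Bc - mu_Aa Theta_Bbc) / 3
        + T_abcd Theta_Aab Theta_Bcd / 9

in units of e^2/Å; multiply by the Coulomb prefactor for kJ/mol.  All routines
are vectorized over an array of pairs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pair_multipole_energy", "pair_moment_gradients", "traceless_quadrupole"]

_EYE = np.eye(3)


def traceless_quadrupole(charges, offsets):
    """Theta = 1/2 sum q (3 d d - d^2 I) of a point-charge cluster."""
    charges = np.asarray(charges, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    dd = np.einsum("i,ia,ib->ab", charges, offsets, offsets)
    return 1.5 * dd - 0.5 * np.trace(dd) * _EYE


def pair_multipole_energy(rvec, q_a, mu_a, th_a, q_b, mu_b, th_b, rank=2):
    """Per-pair electrostatic energies (e^2/Å) for arrays of site pairs.

    ``rvec`` (m, 3) points from site A to site B.  ``rank`` truncates the
    expansion: 0 = charges, 1 = +dipoles, 2 = +quadrupoles.
    """
    if not 0 <= rank <= 2:
        raise ValueError(f"multipole rank {rank} unsupported (0..2 implemented)")
    R = np.asarray(rvec, dtype=float).reshape(-1, 3)
    m = R.shape[0]
    r2 = np.einsum("ma,ma->m", R, R)
    r = np.sqrt(r2)
    if np.any(r <= 0):
        raise ValueError("zero separation in pair list")
    inv_r = 1.0 / r

    q_a = np.broadcast_to(np.asarray(q_a, dtype=float), (m,))
    q_b = np.broadcast_to(np.asarray(q_b, dtype=float), (m,))
    energy = q_a * q_b * inv_r
    if rank == 0:
        return energy

    mu_a = np.broadcast_to(np.asarray(mu_a, dtype=float), (m, 3))
    mu_b = np.broadcast_to(np.asarray(mu_b, dtype=float), (m, 3))
    inv_r3 = inv_r / r2
    t1 = -R * inv_r3[:, None]  # T_a
    energy = energy + np.einsum("ma,ma->m", t1, q_a[:, None] * mu_b - mu_a * q_b[:, None])

    inv_r5 = inv_r3 / r2
    t2 = 3.0 * np.einsum("ma,mb->mab", R, R) * inv_r5[:, None, None] \
        - r2[:, None, None] * inv_r5[:, None, None] * _EYE
    energy = energy - np.einsum("mab,ma,mb->m", t2, mu_a, mu_b)
    if rank == 1:
        return energy

    th_a = np.broadcast_to(np.asarray(th_a, dtype=float), (m, 3, 3))
    th_b = np.broadcast_to(np.asarray(th_b, dtype=float), (m, 3, 3))
    energy = energy + np.einsum("mab,mab->m", t2, q_a[:, None, None] * th_b + th_a * q_b[:, None, None]) / 3.0

    inv_r7 = inv_r5 / r2
    rrr = np.einsum("ma,mb,mc->mabc", R, R, R)
    r_delta = (
        np.einsum("ma,bc->mabc", R, _EYE)
        + np.einsum("mb,ac->mabc", R, _EYE)
        + np.einsum("mc,ab->mabc", R, _EYE)
    )
    t3 = -3.0 * (5.0 * rrr - r2[:, None, None, None] * r_delta) * inv_r7[:, None, None, None]
    energy = energy + np.einsum("mabc,mab,mc->m", t3, th_a, mu_b) / 3.0
    energy = energy - np.einsum("mabc,ma,mbc->m", t3, mu_a, th_b) / 3.0

    inv_r9 = inv_r7 / r2
    rrrr = np.einsum("mab,mc,md->mabcd", np.einsum("ma,mb->mab", R, R), R, R)
    dd_rr = (
        np.einsum("ab,mc,md->mabcd", _EYE, R, R)
        + np.einsum("ac,mb,md->mabcd", _EYE, R, R)
        + np.einsum("ad,mb,mc->mabcd", _EYE, R, R)
        + np.einsum("bc,ma,md->mabcd", _EYE, R, R)
        + np.einsum("bd,ma,mc->mabcd", _EYE, R, R)
        + np.einsum("cd,ma,mb->mabcd", _EYE, R, R)
    )
    dddd = (
        np.einsum("ab,cd->abcd", _EYE, _EYE)
        + np.einsum("ac,bd->abcd", _EYE, _EYE)
        + np.einsum("ad,bc->abcd", _EYE, _EYE)
    )
    t4 = (
        105.0 * rrrr
        - 15.0 * r2[:, None, None, None, None] * dd_rr
        + 3.0 * (r2**2)[:, None, None, None, None] * dddd[None]
    ) * inv_r9[:, None, None, None, None]
    energy = energy + np.einsum("mabcd,mab,mcd->m", t4, th_a, th_b) / 9.0
    return energy


def _t_tensors(R, rank):
    """Interaction tensors T^(0..rank+2) = grad^n (1/R) for an (m, 3) array."""
    r2 = np.einsum("ma,ma->m", R, R)
    r = np.sqrt(r2)
    if np.any(r <= 0):
        raise ValueError("zero separation in pair list")
    inv_r = 1.0 / r
    out = {0: inv_r}
    inv_r3 = inv_r / r2
    out[1] = -R * inv_r3[:, None]
    inv_r5 = inv_r3 / r2
    out[2] = 3.0 * np.einsum("ma,mb->mab", R, R) * inv_r5[:, None, None] \
        - r2[:, None, None] * inv_r5[:, None, None] * _EYE
    if rank < 1:
        return out
    inv_r7 = inv_r5 / r2
    rrr = np.einsum("ma,mb,mc->mabc", R, R, R)
    r_delta = (
        np.einsum("ma,bc->mabc", R, _EYE)
        + np.einsum("mb,ac->mabc", R, _EYE)
        + np.einsum("mc,ab->mabc", R, _EYE)
    )
    out[3] = -3.0 * (5.0 * rrr - r2[:, None, None, None] * r_delta) * inv_r7[:, None, None, None]
    if rank < 2:
        return out
    inv_r9 = inv_r7 / r2
    rr = np.einsum("ma,mb->mab", R, R)
    rrrr = np.einsum("mab,mc,md->mabcd", rr, R, R)
    dd_rr = (
        np.einsum("ab,mc,md->mabcd", _EYE, R, R)
        + np.einsum("ac,mb,md->mabcd", _EYE, R, R)
        + np.einsum("ad,mb,mc->mabcd", _EYE, R, R)
        + np.einsum("bc,ma,md->mabcd", _EYE, R, R)
        + np.einsum("bd,ma,mc->mabcd", _EYE, R, R)
        + np.einsum("cd,ma,mb->mabcd", _EYE, R, R)
    )
    dddd = (
        np.einsum("ab,cd->abcd", _EYE, _EYE)
        + np.einsum("ac,bd->abcd", _EYE, _EYE)
        + np.einsum("ad,bc->abcd", _EYE, _EYE)
    )
    out[4] = (
        105.0 * rrrr
        - 15.0 * r2[:, None, None, None, None] * dd_rr
        + 3.0 * (r2**2)[:, None, None, None, None] * dddd[None]
    ) * inv_r9[:, None, None, None, None]
    return out


def pair_moment_gradients(rvec, q_a, mu_a, th_a, q_b, mu_b, th_b, rank=2):
    """d U / d moments for both sides of every pair, U in e^2/Å.

    Returns a dict with keys ``qa, mua, tha, qb, mub, thb``; entries for ranks
    above ``rank`` are zero.  Because U is bilinear in the two sites' moments,
    these gradients are exact (not finite differences).
    """
    if not 0 <= rank <= 2:
        raise ValueError(f"multipole rank {rank} unsupported (0..2 implemented)")
    R = np.asarray(rvec, dtype=float).reshape(-1, 3)
    m = R.shape[0]
    q_a = np.broadcast_to(np.asarray(q_a, dtype=float), (m,))
    q_b = np.broadcast_to(np.asarray(q_b, dtype=float), (m,))
    mu_a = np.broadcast_to(np.asarray(mu_a, dtype=float), (m, 3))
    mu_b = np.broadcast_to(np.asarray(mu_b, dtype=float), (m, 3))
    th_a = np.broadcast_to(np.asarray(th_a, dtype=float), (m, 3, 3))
    th_b = np.broadcast_to(np.asarray(th_b, dtype=float), (m, 3, 3))
    T = _t_tensors(R, rank)
    g = {
        "qa": T[0] * q_b,
        "qb": T[0] * q_a,
        "mua": np.zeros((m, 3)),
        "mub": np.zeros((m, 3)),
        "tha": np.zeros((m, 3, 3)),
        "thb": np.zeros((m, 3, 3)),
    }
    if rank >= 1:
        g["qa"] += np.einsum("ma,ma->m", T[1], mu_b)
        g["qb"] -= np.einsum("ma,ma->m", T[1], mu_a)
        g["mua"] = -T[1] * q_b[:, None] - np.einsum("mab,mb->ma", T[2], mu_b)
        g["mub"] = T[1] * q_a[:, None] - np.einsum("mab,ma->mb", T[2], mu_a)
    if rank >= 2:
        g["qa"] += np.einsum("mab,mab->m", T[2], th_b) / 3.0
        g["qb"] += np.einsum("mab,mab->m", T[2], th_a) / 3.0
        g["mua"] -= np.einsum("mabc,mbc->ma", T[3], th_b) / 3.0
        g["mub"] += np.einsum("mabc,mab->mc", T[3], th_a) / 3.0
        g["tha"] = (
            T[2] * q_b[:, None, None] / 3.0
            + np.einsum("mabc,mc->mab", T[3], mu_b) / 3.0
            + np.einsum("mabcd,mcd->mab", T[4], th_b) / 9.0
        )
        g["thb"] = (
            T[2] * q_a[:, None, None] / 3.0
            - np.einsum("mabc,ma->mbc", T[3], mu_a) / 3.0
            + np.einsum("mabcd,mab->mcd", T[4], th_a) / 9.0
        )
    return g
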