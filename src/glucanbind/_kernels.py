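"""Numba kernels for Brownian dynamics and adaptive-biasing-force sampling.

All kernels use the overdamped Euler-Maruyama update

    x(t+dt) = x(t) + (D/kBT) * F * dt + sqrt(2 D dt) * xi,   xi ~ N(0, 1)

with minimum-image distances in a periodic box centred on the origin.
Randomness is numba's per-thread Mersenne Twister seeded at kernel entry, so
identical seeds give bit-identical streams.

Potential parameter packing (``pp`` array):
    0 rep_A     soft-core wall height (kcal/mol)
    1 rep_lam   soft-core wall width (Å)
    2 ns_eps    nonspecific surface attraction depth (kcal/mol)
    3 ns_w      nonspecific shell width (Å)
    4 depth     binding-site Gaussian well depth (kcal/mol)
    5-7 wx,wy,wz  site widths per axis (Å)
    8 bond_k    harmonic bond stiffness (kcal/mol/Å²)
    9 bond_b    equilibrium bond length (Å)

Restraint parameter packing (``rp`` array, single-molecule stages):
    0 wall_k, 1 wall_r0          flat-bottom radial wall about the site
    2 kpth, 3 th0                polar-angle restraint of the tracked monomer
    4 kpph, 5 ph0                azimuth restraint of the tracked monomer
    6 conf_k                     bond-length RMSD restraint (harmonic)
    7 axT_k, 8 axT0              chain-axis polar restraint
    9 axP_k, 10 axP0             chain-axis azimuth restraint
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0


@njit(cache=False, inline="always")
def _mi(d, L):
    # minimum-image displacement component
    return d - L * math.floor(d / L + 0.5)


@njit(cache=False)
def _forces(pos, F, bead_c, bead_R, site_c, pp, n_mon, box):
    """System potential energy; forces accumulated into F (not zeroed)."""
    n = pos.shape[0]
    nb = bead_c.shape[0]
    rep_A = pp[0]
    rep_lam = pp[1]
    ns_eps = pp[2]
    ns_w = pp[3]
    depth = pp[4]
    bond_k = pp[8]
    bond_b = pp[9]
    U = 0.0
    for i in range(n):
        for b in range(nb):
            dx = _mi(pos[i, 0] - bead_c[b, 0], box[0])
            dy = _mi(pos[i, 1] - bead_c[b, 1], box[1])
            dz = _mi(pos[i, 2] - bead_c[b, 2], box[2])
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-9:
                U += rep_A
                continue
            s = d - bead_R[b]
            dudd = 0.0
            t = s / rep_lam
            if t < 40.0:
                e = math.exp(t)
                sig = 1.0 / (1.0 + e)
                U += rep_A * sig
                dudd += -rep_A * e * sig * sig / rep_lam
            if ns_eps != 0.0:
                q = s * s / (2.0 * ns_w * ns_w)
                if q < 60.0:
                    g = math.exp(-q)
                    U += -ns_eps * g
                    dudd += ns_eps * g * s / (ns_w * ns_w)
            f = -dudd / d
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[i, 2] += f * dz
        if depth != 0.0:
            dx = _mi(pos[i, 0] - site_c[0], box[0])
            dy = _mi(pos[i, 1] - site_c[1], box[1])
            dz = _mi(pos[i, 2] - site_c[2], box[2])
            qx = dx / pp[5]
            qy = dy / pp[6]
            qz = dz / pp[7]
            q = 0.5 * (qx * qx + qy * qy + qz * qz)
            if q < 60.0:
                g = depth * math.exp(-q)
                U += -g
                F[i, 0] += -g * dx / (pp[5] * pp[5])
                F[i, 1] += -g * dy / (pp[6] * pp[6])
                F[i, 2] += -g * dz / (pp[7] * pp[7])
    if n_mon > 1 and bond_k != 0.0:
        n_mol = n // n_mon
        for m in range(n_mol):
            base = m * n_mon
            for j in range(n_mon - 1):
                i1 = base + j
                i2 = i1 + 1
                dx = _mi(pos[i2, 0] - pos[i1, 0], box[0])
                dy = _mi(pos[i2, 1] - pos[i1, 1], box[1])
                dz = _mi(pos[i2, 2] - pos[i1, 2], box[2])
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d < 1e-12:
                    continue
                dev = d - bond_b
                U += 0.5 * bond_k * dev * dev
                f = -bond_k * dev / d
                F[i2, 0] += f * dx
                F[i2, 1] += f * dy
                F[i2, 2] += f * dz
                F[i1, 0] -= f * dx
                F[i1, 1] -= f * dy
                F[i1, 2] -= f * dz
    return U


@njit(cache=False)
def _restraint_forces(pos, F, site_c, rp, m_idx, n_mon, pp, box):
    """Stage-protocol restraints for a single ligand molecule. Returns energy."""
    U = 0.0
    wall_k = rp[0]
    # tracked-monomer displacement from the site centre
    vx = _mi(pos[m_idx, 0] - site_c[0], box[0])
    vy = _mi(pos[m_idx, 1] - site_c[1], box[1])
    vz = _mi(pos[m_idx, 2] - site_c[2], box[2])
    r = math.sqrt(vx * vx + vy * vy + vz * vz)
    if wall_k > 0.0 and r > rp[1]:
        dev = r - rp[1]
        U += 0.5 * wall_k * dev * dev
        f = -wall_k * dev / r
        F[m_idx, 0] += f * vx
        F[m_idx, 1] += f * vy
        F[m_idx, 2] += f * vz
    if (rp[2] > 0.0 or rp[4] > 0.0) and r > 1e-9:
        rho2 = vx * vx + vy * vy
        rho = math.sqrt(rho2)
        if rp[2] > 0.0 and rho > 1e-6:
            th = math.acos(min(1.0, max(-1.0, vz / r)))
            dev = th - rp[3]
            U += 0.5 * rp[2] * dev * dev
            # grad(theta) = (cos th cos ph, cos th sin ph, -sin th)/r
            cth = vz / r
            sth = rho / r
            g = rp[2] * dev / r
            F[m_idx, 0] += -g * cth * (vx / rho)
            F[m_idx, 1] += -g * cth * (vy / rho)
            F[m_idx, 2] += g * sth
        if rp[4] > 0.0 and rho2 > 1e-12:
            ph = math.atan2(vy, vx)
            dev = ph - rp[5]
            # wrap deviation into (-pi, pi]
            dev = dev - 2.0 * math.pi * math.floor(dev / (2.0 * math.pi) + 0.5)
            U += 0.5 * rp[4] * dev * dev
            g = rp[4] * dev / rho2
            F[m_idx, 0] += g * vy
            F[m_idx, 1] += -g * vx
    if rp[6] > 0.0 and n_mon > 1:
        # 0.5*k*xi^2 with xi the bond-length RMSD is separable per bond
        keff = rp[6] / (n_mon - 1)
        bond_b = pp[9]
        for j in range(n_mon - 1):
            dx = _mi(pos[j + 1, 0] - pos[j, 0], box[0])
            dy = _mi(pos[j + 1, 1] - pos[j, 1], box[1])
            dz = _mi(pos[j + 1, 2] - pos[j, 2], box[2])
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-12:
                continue
            dev = d - bond_b
            U += 0.5 * keff * dev * dev
            f = -keff * dev / d
            F[j + 1, 0] += f * dx
            F[j + 1, 1] += f * dy
            F[j + 1, 2] += f * dz
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
            F[j, 2] -= f * dz
    if (rp[7] > 0.0 or rp[9] > 0.0) and n_mon > 1:
        last = n_mon - 1
        ax = _mi(pos[last, 0] - pos[0, 0], box[0])
        ay = _mi(pos[last, 1] - pos[0, 1], box[1])
        az = _mi(pos[last, 2] - pos[0, 2], box[2])
        a = math.sqrt(ax * ax + ay * ay + az * az)
        rho2 = ax * ax + ay * ay
        rho = math.sqrt(rho2)
        if rp[7] > 0.0 and a > 1e-9 and rho > 1e-6:
            Th = math.acos(min(1.0, max(-1.0, az / a)))
            dev = Th - rp[8]
            U += 0.5 * rp[7] * dev * dev
            cth = az / a
            sth = rho / a
            g = rp[7] * dev / a
            gx = -g * cth * (ax / rho)
            gy = -g * cth * (ay / rho)
            gz = g * sth
            F[last, 0] += gx
            F[last, 1] += gy
            F[last, 2] += gz
            F[0, 0] -= gx
            F[0, 1] -= gy
            F[0, 2] -= gz
        if rp[9] > 0.0 and rho2 > 1e-12:
            Ph = math.atan2(ay, ax)
            dev = Ph - rp[10]
            dev = dev - 2.0 * math.pi * math.floor(dev / (2.0 * math.pi) + 0.5)
            U += 0.5 * rp[9] * dev * dev
            g = rp[9] * dev / rho2
            F[last, 0] += g * ay
            F[last, 1] += -g * ax
            F[0, 0] -= g * ay
            F[0, 1] -= -g * ax
    return U


@njit(cache=False)
def bd_run(
    pos0,
    n_steps,
    save_stride,
    dt,
    D,
    kT,
    box,
    seed,
    bead_c,
    bead_R,
    site_c,
    pp,
    n_mon,
    rp,
    m_idx,
    use_restraints,
    max_disp,
    out,
):
    """Unbiased Brownian dynamics; frames written to ``out``.

    Returns 0 on success or -step at the first step whose displacement
    exceeded ``max_disp`` (Å).
    """
    np.random.seed(seed)
    n = pos0.shape[0]
    pos = pos0.copy()
    F = np.zeros((n, 3))
    mob = D / kT
    sig = math.sqrt(2.0 * D * dt)
    for k in range(n):
        for c in range(3):
            out[0, k, c] = pos[k, c]
    ks = 1
    for step in range(1, n_steps + 1):
        for k in range(n):
            F[k, 0] = 0.0
            F[k, 1] = 0.0
            F[k, 2] = 0.0
        _forces(pos, F, bead_c, bead_R, site_c, pp, n_mon, box)
        if use_restraints:
            _restraint_forces(pos, F, site_c, rp, m_idx, n_mon, pp, box)
        for k in range(n):
            for c in range(3):
                disp = mob * F[k, c] * dt + sig * np.random.normal(0.0, 1.0)
                if abs(disp) > max_disp:
                    return -step
                x = pos[k, c] + disp
                L = box[c]
                pos[k, c] = x - L * math.floor(x / L + 0.5)
        if step % save_stride == 0:
            for k in range(n):
                for c in range(3):
                    out[ks, k, c] = pos[k, c]
            ks += 1
    return STATUS_OK


@njit(cache=False)
def bd_run_abf(
    pos0,
    n_steps,
    dt,
    D,
    kT,
    box,
    seed,
    bead_c,
    bead_R,
    site_c,
    pp,
    n_mon,
    rp,
    use_restraints,
    radial,
    m_idx,
    ref,
    axis_idx,
    lo,
    width,
    nbins,
    n_full,
    dom_k,
    counts,
    fsum,
    max_disp,
):
    """Brownian dynamics with adaptive biasing force on 1-3 coordinates.

    ``radial`` selects the distance-to-reference coordinate (with the
    2*kBT/r Jacobian term in the force sample); otherwise ``axis_idx``
    lists the Cartesian components tracked.  ``counts``/``fsum`` are flat
    accumulators (C-order over the bin grid) updated in place.  Half-
    harmonic walls of stiffness ``dom_k`` confine the coordinates to the
    domain; wall and bias forces are excluded from the force samples.
    """
    np.random.seed(seed)
    n = pos0.shape[0]
    d = len(nbins)
    pos = pos0.copy()
    F = np.zeros((n, 3))
    mob = D / kT
    sig = math.sqrt(2.0 * D * dt)
    strides = np.ones(d, dtype=np.int64)
    for k in range(d - 2, -1, -1):
        strides[k] = strides[k + 1] * nbins[k + 1]
    xi = np.zeros(d)
    fs = np.zeros(d)
    for step in range(n_steps):
        for k in range(n):
            F[k, 0] = 0.0
            F[k, 1] = 0.0
            F[k, 2] = 0.0
        _forces(pos, F, bead_c, bead_R, site_c, pp, n_mon, box)
        if use_restraints:
            _restraint_forces(pos, F, site_c, rp, m_idx, n_mon, pp, box)
        vx = _mi(pos[m_idx, 0] - ref[0], box[0])
        vy = _mi(pos[m_idx, 1] - ref[1], box[1])
        vz = _mi(pos[m_idx, 2] - ref[2], box[2])
        if radial:
            r = math.sqrt(vx * vx + vy * vy + vz * vz)
            xi[0] = r
            if r > 1e-9:
                fs[0] = (
                    (F[m_idx, 0] * vx + F[m_idx, 1] * vy + F[m_idx, 2] * vz) / r
                    + 2.0 * kT / r
                )
            else:
                fs[0] = 0.0
        else:
            for k in range(d):
                ai = axis_idx[k]
                if ai == 0:
                    xi[k] = vx
                elif ai == 1:
                    xi[k] = vy
                else:
                    xi[k] = vz
                fs[k] = F[m_idx, ai]
        # locate bin
        flat = 0
        inside = True
        for k in range(d):
            b = int(math.floor((xi[k] - lo[k]) / width))
            if b < 0 or b >= nbins[k]:
                inside = False
                break
            flat += b * strides[k]
        if inside:
            counts[flat] += 1
            nb = counts[flat]
            ramp = nb / n_full if nb < n_full else 1.0
            for k in range(d):
                fsum[flat * d + k] += fs[k]
                bias = -(fsum[flat * d + k] / nb) * ramp
                if radial:
                    r = xi[0]
                    if r > 1e-9:
                        F[m_idx, 0] += bias * vx / r
                        F[m_idx, 1] += bias * vy / r
                        F[m_idx, 2] += bias * vz / r
                else:
                    F[m_idx, axis_idx[k]] += bias
        # domain walls
        for k in range(d):
            dev = 0.0
            if xi[k] < lo[k]:
                dev = lo[k] - xi[k]
            elif xi[k] > lo[k] + nbins[k] * width:
                dev = (lo[k] + nbins[k] * width) - xi[k]
            if dev != 0.0:
                fw = dom_k * dev
                if radial:
                    r = xi[0]
                    if r > 1e-9:
                        F[m_idx, 0] += fw * vx / r
                        F[m_idx, 1] += fw * vy / r
                        F[m_idx, 2] += fw * vz / r
                else:
                    F[m_idx, axis_idx[k]] += fw
        for k in range(n):
            for c in range(3):
                disp = mob * F[k, c] * dt + sig * np.random.normal(0.0, 1.0)
                if abs(disp) > max_disp:
                    return -(step + 1)
                x = pos[k, c] + disp
                L = box[c]
                pos[k, c] = x - L * math.floor(x / L + 0.5)
    return STATUS_OK


@njit(cache=False)
def abf_run_1d_poly(
    x0,
    n_steps,
    dt,
    D,
    kT,
    seed,
    coeffs,
    lo,
    hi,
    width,
    n_full,
    dom_k,
    counts,
    fsum,
    max_disp,
):
    """1D ABF on an analytic quartic potential U(x) = sum_i coeffs[i] x^i."""
    np.random.seed(seed)
    x = x0
    mob = D / kT
    sig = math.sqrt(2.0 * D * dt)
    nbins = len(counts)
    for step in range(n_steps):
        f = -(
            coeffs[1]
            + 2.0 * coeffs[2] * x
            + 3.0 * coeffs[3] * x * x
            + 4.0 * coeffs[4] * x * x * x
        )
        Ftot = f
        b = int(math.floor((x - lo) / width))
        if 0 <= b < nbins:
            counts[b] += 1
            fsum[b] += f
            nb = counts[b]
            ramp = nb / n_full if nb < n_full else 1.0
            Ftot += -(fsum[b] / nb) * ramp
        if x < lo:
            Ftot += dom_k * (lo - x)
        elif x > hi:
            Ftot += dom_k * (hi - x)
        disp = mob * Ftot * dt + sig * np.random.normal(0.0, 1.0)
        if abs(disp) > max_disp:
            return -(step + 1)
        x += disp
    return STATUS_OK
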