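"""Numba kernel for the overdamped-Langevin integrator.

The kernel advances one point ligand through a chunk of pre-drawn Gaussian
displacements.  All randomness is generated outside (NumPy Generator), so
trajectories are bit-reproducible for a fixed seed irrespective of chunking
— the chunk size is a fixed constant in :mod:`cgbind.synthetic`.

Potential codes: 0 flat, 1 smoothed square well, 2 Gaussian well.  The
square well is smoothed by a half-cosine ramp of width ``ramp`` so the
force stays finite::

    U(r) = -eps                          r < r_w
         = -eps/2 (1 + cos(pi (r-r_w)/ramp))   r_w <= r < r_w + ramp
         = 0                             otherwise
"""

import math

import numba


@numba.njit(cache=False)
def advance_chunk(
    pos, upos, noise,
    code, eps, width, ramp,
    cx, cy, cz, lx, ly, lz,
    mobility_dt,            # D*dt/RT, nm^2 mol kJ^-1
    stride, step0,
    out_wrapped, out_unwrapped, out_k,
):
    """Advance ``noise.shape[0]`` steps in place; return updated sample count."""
    n = noise.shape[0]
    k = out_k
    for i in range(n):
        dx = pos[0] - cx
        dy = pos[1] - cy
        dz = pos[2] - cz
        dx -= lx * round(dx / lx)
        dy -= ly * round(dy / ly)
        dz -= lz * round(dz / lz)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)

        dudr = 0.0
        if code == 1:
            if width <= r < width + ramp:
                dudr = 0.5 * eps * math.pi / ramp * math.sin(math.pi * (r - width) / ramp)
        elif code == 2:
            s2 = width * width
            dudr = eps * (r / s2) * math.exp(-0.5 * r * r / s2)

        fx = fy = fz = 0.0
        if dudr != 0.0 and r > 1e-12:
            scale = -mobility_dt * dudr / r
            fx = scale * dx
            fy = scale * dy
            fz = scale * dz

        sx = fx + noise[i, 0]
        sy = fy + noise[i, 1]
        sz = fz + noise[i, 2]

        upos[0] += sx
        upos[1] += sy
        upos[2] += sz
        pos[0] += sx
        pos[1] += sy
        pos[2] += sz
        pos[0] -= lx * math.floor(pos[0] / lx)
        pos[1] -= ly * math.floor(pos[1] / ly)
        pos[2] -= lz * math.floor(pos[2] / lz)

        if (step0 + i + 1) % stride == 0:
            out_wrapped[k, 0] = pos[0]
            out_wrapped[k, 1] = pos[1]
            out_wrapped[k, 2] = pos[2]
            out_unwrapped[k, 0] = upos[0]
            out_unwrapped[k, 1] = upos[1]
            out_unwrapped[k, 2] = upos[2]
            k += 1
    return k
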