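"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own numerical paths: eigenproblems are
solved with generic dense solvers (batched ``numpy.linalg.eigh`` or explicit
Jacobi rotations), trilinear interpolation is hand-rolled, and spanning
forests are found by exhaustive enumeration.
"""

from itertools import combinations

import numpy as np

from skeletrace.tensor import hessian


def jacobi_eigenvalues(A, sweeps=50, tol=1e-14):
    """Eigenvalues of a symmetric 3x3 matrix by classical Jacobi rotations."""
    a = np.array(A, dtype=float)
    for _ in range(sweeps):
        off = np.sqrt(a[0, 1] ** 2 + a[0, 2] ** 2 + a[1, 2] ** 2)
        if off < tol * max(1.0, np.abs(np.diag(a)).max()):
            break
        for p, q in ((0, 1), (0, 2), (1, 2)):
            if a[p, q] == 0.0:
                continue
            theta = (a[q, q] - a[p, p]) / (2.0 * a[p, q])
            t = np.sign(theta) / (np.abs(theta) + np.sqrt(theta**2 + 1.0))
            c = 1.0 / np.sqrt(t**2 + 1.0)
            s = t * c
            J = np.eye(3)
            J[p, p] = J[q, q] = c
            J[p, q] = s
            J[q, p] = -s
            a = J.T @ a @ J
    return np.sort(np.diag(a))


def trilinear(data, p):
    """Trilinear interpolation with clamping, written independently."""
    p = np.clip(p, 0, np.asarray(data.shape) - 1)
    i0 = np.floor(p).astype(int)
    i1 = np.minimum(i0 + 1, np.asarray(data.shape) - 1)
    f = p - i0
    val = 0.0
    for dx in (0, 1):
        wx = f[0] if dx else 1 - f[0]
        for dy in (0, 1):
            wy = f[1] if dy else 1 - f[1]
            for dz in (0, 1):
                wz = f[2] if dz else 1 - f[2]
                val += wx * wy * wz * data[
                    i1[0] if dx else i0[0],
                    i1[1] if dy else i0[1],
                    i1[2] if dz else i0[2],
                ]
    return val


def brute_force_nms(S, d, delta=1.0 / 3.0, threshold=0.0):
    """Literal strict-maximum probing along the top 3-d eigendirections.

    Eigenvectors come from a generic dense symmetric eigensolver, sorted by
    descending absolute eigenvalue; probes use the local trilinear above.
    Returns the skeleton as a set of integer voxel tuples.
    """
    data = np.asarray(S.data, dtype=np.float64)
    H = hessian(S)
    nx, ny, nz = data.shape
    comps = [np.asarray(c) for c in H.components()]
    interior = [
        (x, y, z)
        for x in range(1, nx - 1)
        for y in range(1, ny - 1)
        for z in range(1, nz - 1)
        if data[x, y, z] >= threshold
    ]
    if not interior:
        return set()
    idx = tuple(np.array(interior).T)
    mats = np.empty((len(interior), 3, 3))
    xx, yy, zz, xy, xz, yz = (c[idx] for c in comps)
    mats[:, 0, 0] = xx
    mats[:, 1, 1] = yy
    mats[:, 2, 2] = zz
    mats[:, 0, 1] = mats[:, 1, 0] = xy
    mats[:, 0, 2] = mats[:, 2, 0] = xz
    mats[:, 1, 2] = mats[:, 2, 1] = yz
    w, v = np.linalg.eigh(mats)
    order = np.argsort(-np.abs(w), axis=1)
    out = set()
    for i, (x, y, z) in enumerate(interior):
        s = data[x, y, z]
        pos = np.array([x, y, z], dtype=float)
        ok = True
        for j in order[i, : 3 - d]:
            vj = v[i, :, j]
            if not (s > trilinear(data, pos + delta * vj) and s > trilinear(data, pos - delta * vj)):
                ok = False
                break
        if ok:
            out.add((x, y, z))
    return out


def brute_force_msf_weight(nodes, edges):
    """Minimum spanning forest weight by exhaustive edge-subset enumeration.

    ``edges`` is a list of (u, v, w).  Feasible for <= ~8 nodes.
    """
    nodes = list(nodes)
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}

    def n_components(sub):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for u, v, _ in sub:
            ru, rv = find(index[u]), find(index[v])
            if ru != rv:
                parent[ru] = rv
        return len({find(i) for i in range(n)})

    k_min = n_components(edges)
    need = n - k_min
    best = np.inf
    for sub in combinations(edges, need):
        if n_components(list(sub)) == k_min:
            best = min(best, sum(w for _, _, w in sub))
    return 0.0 if need == 0 else float(best)
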