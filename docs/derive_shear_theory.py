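"""Derivation of the first-order capsule-in-shear theory.

Steady small-deformation state of an initially spherical capsule with a
Kelvin-Voigt membrane (linearised SK elasticity: shear modulus Gs, area
modulus kappa*Gs with kappa = 1+2C; surface shear viscosity mu_s,
dilatational surface viscosity zero) in unbounded simple shear
u = (gdot y, 0, 0), Stokes flow, inner viscosity ratio lambda = O(1).

Scalings (a = mu0 = gdot = 1): strain e = Ca*eh, shape r = 1 + Ca*jh*S,
membrane velocity = W x + Ca*vh.  Leading order interface velocity is the
rigid rotation W x (steady membrane => surface isometry), so the O(1)
outer flow is the classical rigid-sphere-in-shear solution and the inner
fluid is in rigid rotation (=> lambda drops out at this order).

System of 8 unknowns per the two l=2 patterns A1 (shear) and A2 (45 deg):
  eh = p*F1 + q*F2 per pattern,  F1 = dev in-plane pattern, F2 = S*P
  jh = shape amplitude, w = tangential tank-treading velocity amplitude
Equations: membrane traction balance (tangential + normal) and steady
co-rotational strain transport  (W x . grad) eh - W eh + eh W = D_s(vh).

Output: matrices M0, Mk (kappa terms), Mb (beta = eta* Ca terms), rhs b,
so that M(kappa, beta) u = b, and D/Ca = hypot(j1, j2)/2.
"""
import numpy as np
import sympy as sp

x, y, z = sp.symbols("x y z", real=True)
X = sp.Matrix([x, y, z])
r = sp.sqrt(x * x + y * y + z * z)
xh = X / r
half = sp.Rational(1, 2)
A1 = sp.Matrix([[0, half, 0], [half, 0, 0], [0, 0, 0]])
A2 = sp.Matrix([[half, 0, 0], [0, -half, 0], [0, 0, 0]])
W = sp.Matrix([[0, half, 0], [-half, 0, 0], [0, 0, 0]])
E = A1
P = sp.eye(3) - xh * xh.T


def S_hat(A):
    return (xh.T * A * xh)[0]


def grad_vec(u):
    return sp.Matrix(3, 3, lambda i, j: sp.diff(u[i], X[j]))


def e_op(u):
    G = grad_vec(u)
    return sp.simplify(P * (G + G.T) * P / 2)


def div_s(tau):
    out = []
    for i in range(3):
        s = 0
        for j in range(3):
            for k in range(3):
                s += P[j, k] * sp.diff(tau[i, j], X[k])
        out.append(sp.simplify(s))
    return sp.Matrix(out)


def dev_inplane(t):
    return sp.simplify(t - sp.trace(t) * P / 2)


# --- sanity: div_s of isotropic tension T*P = -2 T xh --------------------
chk = div_s(P)
pt = {x: 0.3, y: -0.5, z: sp.sqrt(1 - 0.34)}
v = np.array([float(c.subs(pt)) for c in chk])
xp = np.array([0.3, -0.5, float(sp.sqrt(1 - 0.34))])
assert np.allclose(v, -2 * xp, atol=1e-12), v

# --- leading-order outer flow: rigid sphere in shear ---------------------
Sx = (X.T * E * X)[0]            # unnormalised x.E.x
cP, cT, cpr = sp.symbols("cP cT cpr")
u_inf = (E + W) * X
u_P = sp.Matrix([sp.diff(Sx / r**5, X[i]) for i in range(3)])
u_T = Sx * X / r**5
u0 = u_inf + cP * u_P + cT * u_T
p0 = cpr * Sx / r**5

# Stokes: grad p = lap u, div u = 0
lap = sp.Matrix([sum(sp.diff(u0[i], X[j], 2) for j in range(3))
                 for i in range(3)])
gp = sp.Matrix([sp.diff(p0, X[i]) for i in range(3)])
divu = sum(sp.diff(u0[i], X[i]) for i in range(3))
eqs = [sp.simplify(divu)]
mom = sp.simplify(lap - gp)
# sample a point to extract conditions
sols = sp.solve([mom[i].subs({x: sp.Rational(1, 3), y: sp.Rational(1, 5),
                              z: sp.Rational(1, 7)}) for i in range(3)]
                + [sp.Eq((u0[i] - (W * X)[i]).subs({x: 1, y: 0, z: 0}), 0)
                   for i in range(3)]
                + [sp.Eq((u0[i] - (W * X)[i]).subs(
                    {x: sp.Rational(3, 5), y: sp.Rational(4, 5), z: 0}), 0)
                   for i in range(3)],
                [cP, cT, cpr], dict=True)
assert len(sols) == 1, sols
sol = sols[0]
print("outer flow coefficients:", sol)
u0 = sp.simplify(u0.subs(sol))
p0 = p0.subs(sol)
assert sp.simplify(divu.subs(sol)) == 0

# verify BC u0(r=1) = W x at random unit points
rng = np.random.default_rng(42)
pts = rng.standard_normal((24, 3))
pts /= np.linalg.norm(pts, axis=1, keepdims=True)
f_u0 = sp.lambdify((x, y, z), u0, "numpy")
for p_ in pts[:5]:
    got = np.array(f_u0(*p_), dtype=float).ravel()
    want = np.array([p_[1] / 2, -p_[0] / 2, 0.0])
    assert np.allclose(got, want, atol=1e-10), (got, want)
print("outer BC verified (rigid rotation at r=1)")

# traction of the leading flow on r=1 (inner side: rigid rotation, zero)
G0 = grad_vec(u0)
sigma = -p0 * sp.eye(3) + (G0 + G0.T)
t0 = sigma * xh     # traction vector; evaluate at r=1

# --- basis fields --------------------------------------------------------
def t_field(A):
    return A * xh - S_hat(A) * xh


def F1(A):
    return dev_inplane(P * A * P)


def F2(A):
    return S_hat(A) * P


vec_basis = [t_field(A1), t_field(A2), S_hat(A1) * xh, S_hat(A2) * xh]
ten_basis = [F1(A1), F1(A2), F2(A1), F2(A2)]

f_vecb = [sp.lambdify((x, y, z), b, "numpy") for b in vec_basis]
f_tenb = [sp.lambdify((x, y, z), b, "numpy") for b in ten_basis]


def project(field_fn, basis_fns, label):
    """Least-squares projection of a field onto basis at unit sample pts."""
    rows = []
    for p_ in pts:
        rows.append(np.array(field_fn(*p_), dtype=float).ravel())
    Fv = np.concatenate(rows)
    Bm = []
    for bf in basis_fns:
        Bm.append(np.concatenate(
            [np.array(bf(*p_), dtype=float).ravel() for p_ in pts]))
    Bm = np.array(Bm).T
    coef, res, *_ = np.linalg.lstsq(Bm, Fv, rcond=None)
    resid = np.linalg.norm(Bm @ coef - Fv) / max(np.linalg.norm(Fv), 1e-30)
    if np.linalg.norm(Fv) > 1e-12:
        assert resid < 1e-8, (label, resid)
    return coef


# --- unknown fields ------------------------------------------------------
# eh = p1 F1(A1) + q1 F2(A1) + p2 F1(A2) + q2 F2(A2)
# vh = w1 t(A1) + w2 t(A2) + v_n xh,  v_n = (W x . grad)(jh S) at r=1
#   (W x . grad) S_A1 = -S_A2 ;  (W x . grad) S_A2 = +S_A1
Omx = W * X                      # rotation velocity (= Omega cross x)


def advect(field):
    """(W x . grad) field, entrywise."""
    if isinstance(field, sp.Matrix) and field.shape[1] == 1:
        return sp.Matrix([sum(Omx[j] * sp.diff(field[i], X[j])
                              for j in range(3)) for i in range(3)])
    return sp.Matrix(field.shape[0], field.shape[1],
                     lambda i, j: sum(Omx[k] * sp.diff(field[i, j], X[k])
                                      for k in range(3)))


# verify scalar advection pattern coupling
adv_S1 = sp.simplify(advect(sp.Matrix([S_hat(A1), 0, 0]))[0])
assert sp.simplify(adv_S1 + S_hat(A2)) == 0
print("advection coupling verified: (Wx.grad) S1 = -S2")

# transport operator on a tensor field: (Wx.grad)eh - W eh + eh W
def transport(ten):
    return advect(ten) - W * ten + ten * W


# membrane velocity perturbation given (w1, w2, j1, j2) symbolically
w1, w2, j1, j2 = sp.symbols("w1 w2 j1 j2")
p1, q1, p2, q2 = sp.symbols("p1 p2 q1 q2")[0:2] + sp.symbols("p2 q2")
p1, q1 = sp.symbols("p1 q1")
p2, q2 = sp.symbols("p2 q2")

v_n = -j1 * S_hat(A2) + j2 * S_hat(A1)
vh = w1 * t_field(A1) + w2 * t_field(A2) + v_n * xh
eh = p1 * F1(A1) + q1 * F2(A1) + p2 * F1(A2) + q2 * F2(A2)

D_m = e_op(vh)                       # membrane strain rate (scaled)
tau_el = 2 * (p1 * F1(A1) + p2 * F1(A2)) \
    + 2 * (q1 * S_hat(A1) + q2 * S_hat(A2)) * P   # kappa multiplies this q-part
# NOTE: tau = 2 eh_dev + kappa tr(eh) P ; tr(eh) = 2 q S
tau_el_dev = 2 * (p1 * F1(A1) + p2 * F1(A2))
tau_el_iso = 2 * (q1 * S_hat(A1) + q2 * S_hat(A2)) * P
tau_visc = 2 * dev_inplane(D_m)      # beta multiplies this

unknowns = [p1, q1, p2, q2, j1, j2, w1, w2]

# --- assemble ------------------------------------------------------------
# traction rows (4): project [t0 + div_s(tau)] on vec_basis = 0
# transport rows (4): project [transport(eh) - D_m] on ten_basis = 0
def lam_field(expr):
    return sp.lambdify((x, y, z), expr, "numpy")


div_dev = div_s(tau_el_dev)
div_iso = div_s(tau_el_iso)
div_visc = div_s(tau_visc)
tr_eh = transport(eh)

M0 = np.zeros((8, 8))
Mk = np.zeros((8, 8))
Mb = np.zeros((8, 8))
b = np.zeros(8)

subs0 = {u: 0 for u in unknowns}
# rhs: -t0 projected
b[:4] = -project(lam_field(t0), f_vecb, "t0")
print("t0 projection:", b[:4])

for col, u in enumerate(unknowns):
    sub = dict(subs0)
    sub[u] = 1
    M0[:4, col] += project(lam_field(div_dev.subs(sub)), f_vecb, "dev")
    Mk[:4, col] += project(lam_field(div_iso.subs(sub)), f_vecb, "iso")
    Mb[:4, col] += project(lam_field(div_visc.subs(sub)), f_vecb, "visc")
    M0[4:, col] += project(lam_field(tr_eh.subs(sub)), f_tenb, "transport")
    M0[4:, col] -= project(lam_field(D_m.subs(sub)), f_tenb, "Dm")

np.set_printoptions(precision=6, suppress=True, linewidth=120)
print("M0=\n", M0)
print("Mk=\n", Mk)
print("Mb=\n", Mb)
print("b=", b)


def solve(kappa, beta):
    M = M0 + kappa * Mk + beta * Mb
    u = np.linalg.solve(M, b)
    return u


for kappa, beta in [(3.0, 0.0), (21.0, 0.0), (3.0, 0.5), (3.0, 2.0),
                    (21.0, 2.0)]:
    u = solve(kappa, beta)
    jj1, jj2 = u[4], u[5]
    DoverCa = 0.5 * np.hypot(jj1, jj2)
    ang = 0.5 * np.degrees(np.arctan2(jj2, jj1))
    print(f"kappa={kappa:5.1f} beta={beta:4.1f}  D/Ca={DoverCa:.6f} "
          f"angle={45 - ang if False else ang:.2f} u={u}")

# try to rationalise the matrices
import fractions
def ratmat(M):
    out = []
    for v in M.ravel():
        fr = fractions.Fraction(v).limit_denominator(10000)
        assert abs(float(fr) - v) < 1e-9, (v, fr)
        out.append(fr)
    return np.array(out).reshape(M.shape)

for name, M in [("M0", M0), ("Mk", Mk), ("Mb", Mb), ("b", b)]:
    R = ratmat(M)
    print(name, "=", [[str(f) for f in row] for row in np.atleast_2d(R)])
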