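"""Independent straight-line oracles used to cross-check the package.

Everything here is written directly from the index definitions with plain
numpy, deliberately sharing no code path with facesym's implementation
(different distance-to-line formulations, explicit loops, explicit
covariance sums).
"""

import numpy as np

from facesym.landmarks import LandmarkFrame, MotionSegment, Recording


def _d(a, b):
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def oracle_indices(rec, forehead_geom, mouth_geom):
    """(forehead index, mouth index) recomputed step by step from the defs."""

    def pts(label):
        seg = rec.segments[label]
        return [f.points for f in rec.frames[seg.start:seg.end]]

    def fore_region(P):
        leb, reb = P[0:5].mean(0), P[5:10].mean(0)
        lec, rec_ = P[19:25].mean(0), P[25:31].mean(0)
        return _d(leb, lec), _d(reb, rec_)

    def mouth_region(P):
        mid = [P[34], P[40], P[44], P[47]]
        dlm = sum(_d(P[31], m) for m in mid) / 4.0
        drm = sum(_d(P[37], m) for m in mid) / 4.0
        return dlm, drm

    def axes(P):
        p23, p26 = P[22], P[25]
        u = p26 - p23
        u = u / np.linalg.norm(u)
        em = (p23 + p26) / 2.0
        return u, em

    def fore_axis(P):
        u, em = axes(P)

        def dist(p):  # perpendicular distance via the 2D cross product
            v = p - em
            return abs(u[0] * v[1] - u[1] * v[0])

        return dist(P[0:5].mean(0)), dist(P[5:10].mean(0))

    def mouth_axis(P):
        u, em = axes(P)

        def dist(p):  # distance to the perpendicular through em = |proj on u|
            return abs(float(np.dot(p - em, u)))

        return dist(P[31]), dist(P[37])

    ffun = fore_region if forehead_geom == "region" else fore_axis
    mfun = mouth_region if mouth_geom == "region" else mouth_axis

    def index(fn, motion_label):
        rest = [fn(P) for P in pts("rest")]
        mot = [fn(P) for P in pts(motion_label)]
        r_left = abs(max(v[0] for v in mot) - np.mean([v[0] for v in rest]))
        r_right = abs(max(v[1] for v in mot) - np.mean([v[1] for v in rest]))
        if r_left == r_right == 0.0:
            return 1.0
        if r_left > r_right:
            return r_right / r_left
        return r_left / r_right

    return index(ffun, "raise"), index(mfun, "smile")


def oracle_lda_weights(X, y, pos_label, priors="empirical", ridge=None):
    """Closed-form pooled-covariance LDA written out with explicit sums."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    X1 = X[y == pos_label]
    X0 = X[y != pos_label]
    mu0, mu1 = X0.mean(0), X1.mean(0)
    S = np.zeros((X.shape[1], X.shape[1]))
    for row in X0:
        S += np.outer(row - mu0, row - mu0)
    for row in X1:
        S += np.outer(row - mu1, row - mu1)
    S /= max(len(X) - 2, 1)
    if ridge is not None:
        S = S + ridge * np.eye(S.shape[0])
    w = np.linalg.inv(S) @ (mu1 - mu0)
    log_ratio = np.log(len(X1) / len(X0)) if priors == "empirical" else 0.0
    b = -0.5 * float(w @ (mu0 + mu1)) + log_ratio
    return w, b


def make_random_recording(rng, n_rest=3, n_raise=3, n_smile=3, scale=200.0):
    """A structurally valid recording with fully random landmark positions."""
    n = n_rest + n_raise + n_smile
    frames = [
        LandmarkFrame(points=rng.uniform(0.0, scale, size=(49, 2)), frame_index=i)
        for i in range(n)
    ]
    segments = {
        "rest": MotionSegment("rest", 0, n_rest),
        "raise": MotionSegment("raise", n_rest, n_rest + n_raise),
        "smile": MotionSegment("smile", n_rest + n_raise, n),
    }
    return Recording(subject_id="rand", frames=frames, segments=segments,
                     class_label="normal", fps=30.0)
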