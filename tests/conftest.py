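"""Shared fixtures and finite-difference helpers for the test suite."""

import numpy as np
import pytest

from brainfuse.nn.autograd import Tensor
from brainfuse.synthetic import AgeSignalParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small in-memory cohort for fast IO/training smoke tests."""
    subjects, manifest = generate_cohort(
        12, (20.0, 80.0), AgeSignalParams(), grid_shape=(8, 8, 8),
        psd_shape=(4, 16), seed=7)
    return subjects, manifest


@pytest.fixture(scope="session")
def tiny_cohort_dir(tiny_cohort, tmp_path_factory):
    """The tiny cohort written to disk; returns the manifest path."""
    from brainfuse.synthetic import write_cohort

    subjects, manifest = tiny_cohort
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(subjects, manifest, out)
    return out / "manifest.tsv"


# ---------------------------------------------------------------------------
# finite-difference gradient checking (float64 for FD accuracy)
# ---------------------------------------------------------------------------

def fd_check_inputs(build, arrays, eps=1e-6, rtol=1e-5, atol=1e-8):
    """Check analytic input-gradients of ``build(tensors) -> scalar Tensor``
    against central finite differences. ``arrays`` are float64 ndarrays."""
    arrays = [np.asarray(a, dtype=np.float64) for a in arrays]
    tensors = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    build(tensors).backward()
    for ti, a in enumerate(arrays):
        num = np.zeros_like(a)
        it = np.nditer(a, flags=["multi_index"], op_flags=["readonly"])
        while not it.finished:
            idx = it.multi_index
            vals = []
            for sign in (1.0, -1.0):
                pert = [x.copy() for x in arrays]
                pert[ti][idx] += sign * eps
                vals.append(build([Tensor(x) for x in pert]).item())
            num[idx] = (vals[0] - vals[1]) / (2 * eps)
            it.iternext()
        np.testing.assert_allclose(tensors[ti].grad, num, rtol=rtol, atol=atol,
                                   err_msg=f"input {ti}")


def _walk_modules(module):
    yield module
    for sub in module._modules.values():
        yield from _walk_modules(sub)


def to_float64(module):
    """Cast every parameter and buffer of an nn.Module to float64 in place."""
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
    for mod in _walk_modules(module):
        for name in mod._buffers:
            arr = getattr(mod, name)
            if np.issubdtype(np.asarray(arr).dtype, np.floating):
                object.__setattr__(mod, name, np.asarray(arr, dtype=np.float64))
    return module


def fd_check_params(f, params, rng, eps=1e-6, rtol=1e-4, atol=1e-7,
                    max_entries=6):
    """Check ``p.grad`` (already populated) of each parameter against FD of
    the forward-only closure ``f() -> scalar Tensor``, on a random subset of
    entries. Parameters must be float64."""
    for name, p in params:
        assert p.grad is not None, f"{name}: no gradient accumulated"
        flat = p.data.reshape(-1)
        ana = np.asarray(p.grad).reshape(-1)
        idxs = rng.choice(flat.size, size=min(max_entries, flat.size),
                          replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            fp = f().item()
            flat[i] = orig - eps
            fm = f().item()
            flat[i] = orig
            num = (fp - fm) / (2 * eps)
            np.testing.assert_allclose(
                ana[i], num, rtol=rtol, atol=atol,
                err_msg=f"{name}[{i}]")
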