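"""Optional numba acceleration.

The integrator loops are written as plain scalar Python and compiled with
numba when it is available; without numba they still run, just slowly.
"""

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]) and not kwargs:
            return args[0]

        def wrap(func):
            return func

        return wrap
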