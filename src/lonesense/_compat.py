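"""Optional numba acceleration.

The TreeSHAP recursion is the only numerically heavy pure-Python loop in the
package; everything else is vectorised numpy/pandas.  When numba is available
the hot functions are jit-compiled, otherwise the same code runs as plain
Python (identical results, just slower).
"""

try:  # pragma: no cover - trivial import guard
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]) and not kwargs:
            return args[0]

        def wrap(fn):
            return fn

        return wrap
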