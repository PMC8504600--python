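"""Re-derive the shipped truth-model edge scales.

Runs the one-time calibration that fixes ``DEFAULT_EDGE_SIGMA_MM``: for each
(plane, depth) a root search over the core penumbra scale makes the
volume-averaged, 5-mm-sampled, Makima-refit baseline reproduce the published
mean PWD for this device class.  Prints the solved scales and the achieved
baseline values; paste the dict into ``profile_restore.simulate`` to update
the shipped defaults.
"""

from profile_restore.simulate import _chain_mean_pwd, calibrate_defaults


def main() -> None:
    params = calibrate_defaults()
    print("edge_sigma_mm = {")
    for (plane, depth), sigma in sorted(params.edge_sigma_mm.items()):
        print(f'    ("{plane}", {depth}): {sigma:.10f},')
    print("}")
    print("\nachieved baseline mean PWD (mm):")
    for (plane, depth), sigma in sorted(params.edge_sigma_mm.items()):
        achieved = _chain_mean_pwd(plane, depth, sigma, params)
        print(f"  {plane:5s} depth {depth:4.1f}: {achieved:.3f}")


if __name__ == "__main__":
    main()
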