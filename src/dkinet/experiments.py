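"""End-to-end phantom experiments tying the modules together.

The central experiment mirrors the paired-acquisition design: several
phantom "subjects" are each scanned twice — a degraded two-shell 61-volume
acquisition and a higher-quality three-shell 96-volume acquisition. The
model fit of the reference scan provides the training targets; the CNN
learns to map degraded scans to those targets; held-out subjects then
compare the CNN estimates and the direct model fit of the degraded scan
against the analytic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cnn, dki, evaluation, phantom

__all__ = ["PairedTrainingResult", "run_paired_training_experiment"]


@dataclass
class PairedTrainingResult:
    """Per-scalar metrics of both methods on the held-out subjects."""

    cnn_rmse: dict            # scalar -> mean RMSE over test subjects
    modelfit_rmse: dict
    cnn_psnr: dict
    modelfit_psnr: dict
    loss_history: list
    n_train: int
    n_test: int
    per_subject: list = field(default_factory=list)

    def cnn_wins_rmse(self, scalar: str) -> bool:
        return self.cnn_rmse[scalar] < self.modelfit_rmse[scalar]

    def cnn_wins_psnr(self, scalar: str) -> bool:
        return self.cnn_psnr[scalar] > self.modelfit_psnr[scalar]


def _fit_maps(dwi) -> dki.ScalarMaps:
    return dki.compute_scalars(dki.fit_dki(dwi))


def run_paired_training_experiment(
    seed: int = 0,
    shape: tuple = (16, 16, 16),
    n_train: int = 5,
    n_test: int = 2,
    epochs: int = 30,
    snr: float = 20.0,
    snr_reference: float = 40.0,
    network_spec: cnn.NetworkSpec | None = None,
) -> PairedTrainingResult:
    """Train on paired scans of n_train subjects, evaluate on n_test held out.

    Every subject is an independent dispersion realization of the default
    phantom. Training inputs are the degraded 61-volume scans; training
    targets are the model fits of the 96-volume reference scans (the
    analytic truth is never shown to the network and is used only for the
    final evaluation). Deterministic for a fixed seed.
    """
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(n_train + n_test)]
    train_pairs = []
    test_subjects = []
    for i, sseed in enumerate(subject_seeds):
        spec = phantom.PhantomSpec(shape=shape, snr=snr,
                                   snr_reference=snr_reference, seed=sseed)
        scan1, scan2, truth = phantom.generate_paired_scans(spec)
        if i < n_train:
            train_pairs.append((scan1, _fit_maps(scan2)))
        else:
            truth_maps = dki.compute_scalars(truth, method="truth")
            test_subjects.append((scan1, truth_maps))

    net_spec = network_spec or cnn.NetworkSpec(
        n_input_channels=train_pairs[0][0].scheme.n_volumes, seed=seed)
    network = cnn.build_network(net_spec)
    estimator = cnn.train(network, train_pairs,
                          cnn.TrainingConfig(epochs=epochs, seed=seed))

    scalars = ("FA", "MD", "MK", "KFA")
    acc = {m: {s: [] for s in scalars} for m in
           ("cnn_rmse", "fit_rmse", "cnn_psnr", "fit_psnr")}
    per_subject = []
    for scan1, truth_maps in test_subjects:
        cnn_maps = cnn.predict_scalars(estimator, scan1)
        fit_maps = _fit_maps(scan1)
        report = evaluation.compare_methods(cnn_maps, fit_maps, truth_maps)
        per_subject.append(report)
        for s in scalars:
            acc["cnn_rmse"][s].append(report["cnn"].metrics[s]["rmse"])
            acc["fit_rmse"][s].append(report["model-fit"].metrics[s]["rmse"])
            acc["cnn_psnr"][s].append(report["cnn"].metrics[s]["psnr"])
            acc["fit_psnr"][s].append(report["model-fit"].metrics[s]["psnr"])

    mean = lambda d: {s: float(np.mean(v)) for s, v in d.items()}
    return PairedTrainingResult(
        cnn_rmse=mean(acc["cnn_rmse"]), modelfit_rmse=mean(acc["fit_rmse"]),
        cnn_psnr=mean(acc["cnn_psnr"]), modelfit_psnr=mean(acc["fit_psnr"]),
        loss_history=estimator.loss_history, n_train=n_train, n_test=n_test,
        per_subject=per_subject)
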