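# Registry of candidate pulse-oximetry light sources.
#
# Each component carries the optical key features from its datasheet
# (dominant wavelength, peak wavelength, FWHM; null where the datasheet
# does not report the value) and the parameters measured with a fibre
# spectrometer at the datasheet forward current (peak wavelength, FWHM).
# Commercial finger-probe emitters appear under anonymised names with
# measured parameters only.  All wavelengths/widths in nm.
components:
  - name: LHQ974
    manufacturer: OSRAM
    package: SMD
    bands:
      - channel: red
        datasheet: {lambda_dom: 643, lambda_peak: 660, fwhm: 20}
        measured: {lambda_peak: 657, fwhm: 19}
  - name: SFH4050
    manufacturer: OSRAM
    package: SMD
    bands:
      - channel: ir
        datasheet: {lambda_dom: 850, lambda_peak: 860, fwhm: 30}
        measured: {lambda_peak: 857, fwhm: 21}
  - name: SFH4248
    manufacturer: OSRAM
    package: SMD
    bands:
      - channel: ir
        datasheet: {lambda_dom: 940, lambda_peak: 950, fwhm: 42}
        measured: {lambda_peak: 956, fwhm: 35}
  - name: VSMD66694
    manufacturer: Vishay
    package: SMD
    bands:
      - channel: red
        datasheet: {lambda_dom: null, lambda_peak: 660, lambda_peak_tol: 10, fwhm: 20}
        measured: {lambda_peak: 662, fwhm: 16}
      - channel: ir
        datasheet: {lambda_dom: null, lambda_peak: 940, lambda_peak_tol: 20, fwhm: 40}
        measured: {lambda_peak: 934, fwhm: 57}
  - name: SMT660/890
    manufacturer: Marubeni
    package: SMD
    bands:
      - channel: red
        datasheet: {lambda_dom: null, lambda_peak: 650, lambda_peak_tol: 10, fwhm: 20}
        measured: {lambda_peak: 657, fwhm: 16}
      - channel: ir
        datasheet: {lambda_dom: null, lambda_peak: 890, lambda_peak_tol: 15, fwhm: 75}
        measured: {lambda_peak: 883, fwhm: 46}
  - name: SFH7050
    manufacturer: OSRAM
    package: SMD
    bands:
      - channel: green
        datasheet: {lambda_dom: 530, lambda_dom_tol: 10, lambda_peak: 525, fwhm: 34}
        measured: {lambda_peak: 532, fwhm: 33}
      - channel: red
        datasheet: {lambda_dom: 655, lambda_dom_tol: 3, lambda_peak: 660, fwhm: 17}
        measured: {lambda_peak: 664, fwhm: 15}
      - channel: ir
        datasheet: {lambda_dom: 940, lambda_dom_tol: 10, lambda_peak: 950, fwhm: 42}
        measured: {lambda_peak: 954, fwhm: 44}
  - name: "LED #1"
    manufacturer: '"M"'
    package: SMD
    bands:
      - channel: red
        datasheet: {lambda_dom: 660, lambda_peak: null, fwhm: null}
        measured: {lambda_peak: 660, fwhm: 21}
      - channel: ir
        datasheet: {lambda_dom: 905, lambda_peak: null, fwhm: null}
        measured: {lambda_peak: 899, fwhm: 68}
  - name: "LED #2"
    manufacturer: '"D"'
    package: SMD
    bands:
      - channel: red
        datasheet: {lambda_dom: null, lambda_peak: null, fwhm: null}
        measured: {lambda_peak: 664, fwhm: 22}
      - channel: ir
        datasheet: {lambda_dom: null, lambda_peak: null, fwhm: null}
        measured: {lambda_peak: 895, fwhm: 62}
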