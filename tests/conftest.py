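import numpy as np
import pytest

from qctcalib import CalibrationLine, CTVolume


@pytest.fixture
def identity_line():
    return CalibrationLine(intercept=0.0, slope=1.0, r_squared=1.0, n_points=5)


@pytest.fixture
def toy_line():
    # density = -12.5 + 0.625 * HU, exact on the ESP insert densities
    return CalibrationLine(intercept=-12.5, slope=0.625, r_squared=1.0, n_points=5)


def make_volume(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                orientation=("L", "P", "S"), fill=0.0):
    return CTVolume(
        voxels=np.full(shape, fill, dtype=float),
        spacing=spacing,
        origin=origin,
        orientation=orientation,
    )


def write_dicom_series(directory, slices_hu, *, slope=1.0, intercept=0.0,
                       pixel_spacing=(1.0, 1.0), slice_step=2.0,
                       drop_pixel_spacing_on=None, position_override=None):
    """Write a minimal axial CT DICOM series; HU = stored * slope + intercept."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    for k, stored in enumerate(slices_hu):
        stored = np.asarray(stored, dtype=np.uint16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = stored.shape
        if drop_pixel_spacing_on != k:
            ds.PixelSpacing = [pixel_spacing[0], pixel_spacing[1]]
        z = k * slice_step
        if position_override and k in position_override:
            z = position_override[k]
        ds.ImagePositionPatient = [0.0, 0.0, z]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.SliceThickness = slice_step
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stored.tobytes()
        ds.save_as(directory / f"slice_{k:03d}.dcm", enforce_file_format=True)
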