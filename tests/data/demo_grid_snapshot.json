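{
  "average": {
    "rmse": 7.715990150494994,
    "pfe": 11.548518971459831,
    "mae": 10.327529566337144,
    "entropy": 6.8193890367044805,
    "snr": 24.79888754304737,
    "psnr": 30.382970316822266,
    "cc": 0.9983329512225003,
    "ergas": 6.158363567880498
  },
  "minimum": {
    "rmse": 10.955705829402552,
    "pfe": 16.704028474806076,
    "mae": 10.327529566337144,
    "entropy": 6.751559280463486,
    "snr": 21.753913584117115,
    "psnr": 27.337996357892006,
    "cc": 0.9965170750942376,
    "ergas": 8.74407798924943
  },
  "dwt": {
    "rmse": 5.250658554485921,
    "pfe": 7.8469461686492465,
    "mae": 11.174164484974956,
    "entropy": 6.991921684346014,
    "snr": 28.142445286241887,
    "psnr": 33.72652806001678,
    "cc": 0.9992303256312037,
    "ergas": 4.190708349627922
  },
  "swt": {
    "rmse": 4.4358405421179725,
    "pfe": 6.630574806274889,
    "mae": 10.699791707437372,
    "entropy": 6.976143425411063,
    "snr": 29.607202316754734,
    "psnr": 35.191285090529625,
    "cc": 0.9994504502470267,
    "ergas": 3.5403776125549014
  },
  "dwt+laplacian": {
    "rmse": 28.225129830421572,
    "pfe": 41.501279345661665,
    "mae": 51.61686950369301,
    "entropy": 7.779286155586091,
    "snr": 13.534001869372608,
    "psnr": 19.118084643147505,
    "cc": 0.9784841952183249,
    "ergas": 22.52732414843925
  },
  "dwt+unsharp": {
    "rmse": 7.974192602271338,
    "pfe": 11.880874150321006,
    "mae": 19.04735173006786,
    "entropy": 7.305313659950061,
    "snr": 24.51298641381067,
    "psnr": 30.097069187585564,
    "cc": 0.99823556832885,
    "ergas": 6.364442702397648
  },
  "dwt+lf_dft": {
    "rmse": 20.678977687255923,
    "pfe": 30.63297095743317,
    "mae": 38.29951409437555,
    "entropy": 7.675685274975791,
    "snr": 16.236139542750497,
    "psnr": 21.820222316525392,
    "cc": 0.9882719928497432,
    "ergas": 16.50451339703187
  },
  "swt+laplacian": {
    "rmse": 27.884414667121145,
    "pfe": 41.01020248125482,
    "mae": 51.11407528856986,
    "entropy": 7.781143868612405,
    "snr": 13.639490185415493,
    "psnr": 19.22357295919039,
    "cc": 0.978989922586442,
    "ergas": 22.255389139740565
  },
  "swt+unsharp": {
    "rmse": 7.019771262049557,
    "pfe": 10.46209688790277,
    "mae": 18.20210646165144,
    "entropy": 7.2925141224285195,
    "snr": 25.620261615807088,
    "psnr": 31.204344389581983,
    "cc": 0.9986318100622821,
    "ergas": 5.602690354949092
  },
  "swt+lf_dft": {
    "rmse": 20.43797789126427,
    "pfe": 30.28172365726679,
    "mae": 37.937361841187496,
    "entropy": 7.676133362451754,
    "snr": 16.337962334523368,
    "psnr": 21.922045108298263,
    "cc": 0.9885393138756448,
    "ergas": 16.312164218954393
  }
}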